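"""Bench-side arithmetic: sucrose preference and relative qPCR expression.

Two small, exact formulas used to score the wet-lab arm of a
network-pharmacology study:

* Sucrose preference (SPT, %): from bottle weights before (W1 sucrose,
  W2 water) and after (W3, W4) the test,
  SPT = 100 * (W1 - W3) / ((W1 - W3) + (W2 - W4)) — sucrose consumed as a
  percentage of total fluid consumed.
* Relative expression by the 2^-ddCt method: Ct differences of a target
  gene against a reference gene, in treated versus control samples, give a
  fold change 2^-(dCt_treated - dCt_control).

Batch helpers read TSV tables of replicate measurements and add per-row
values plus per-group mean and SEM; group-level significance testing is a
job for standard statistics routines and is not re-implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "SucroseMeasurement",
    "QpcrQuad",
    "sucrose_preference",
    "sucrose_preference_from_consumption",
    "ddct_fold_change",
    "spt_batch",
    "ddct_batch",
]


@dataclass(frozen=True)
class SucroseMeasurement:
    """Bottle weights (g): sucrose before/after = w1/w3, water = w2/w4."""

    w1: float
    w2: float
    w3: float
    w4: float

    def __post_init__(self):
        if not (self.w1 >= self.w3 >= 0 and self.w2 >= self.w4 >= 0):
            raise ValueError("bottle weights must satisfy w1 >= w3 >= 0 and w2 >= w4 >= 0")


@dataclass(frozen=True)
class QpcrQuad:
    """Ct values of target and reference genes in treated and control samples."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self):
        for v in (self.ct_target_treated, self.ct_ref_treated,
                  self.ct_target_control, self.ct_ref_control):
            if not (math.isfinite(v) and v > 0):
                raise ValueError("Ct values must be finite and > 0")


def sucrose_preference_from_consumption(sucrose: float, water: float) -> float:
    """SPT% from consumed amounts; algebraically identical to the weight form."""
    if sucrose < 0 or water < 0:
        raise ValueError("consumption must be non-negative")
    total = sucrose + water
    if total <= 0:
        raise ValueError("total consumption is zero; preference undefined")
    return 100.0 * sucrose / total


def sucrose_preference(m: SucroseMeasurement) -> float:
    """SPT% = 100 * (w1 - w3) / ((w1 - w3) + (w2 - w4)), in [0, 100]."""
    return sucrose_preference_from_consumption(m.w1 - m.w3, m.w2 - m.w4)


def ddct_fold_change(q: QpcrQuad) -> float:
    """2^-ddCt relative expression (1.0 means no change versus control)."""
    dct_treated = q.ct_target_treated - q.ct_ref_treated
    dct_control = q.ct_target_control - q.ct_ref_control
    return 2.0 ** (-(dct_treated - dct_control))


def _summarise(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    g = df.groupby("group")[value_col]
    out = g.agg(mean="mean", sem="sem", n="count").reset_index()
    return out


def spt_batch(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    """Per-row SPT% from a TSV with columns group, w1, w2, w3, w4.

    Writes the row table with an ``spt`` column to ``path_out`` and a
    ``<path_out>.summary.tsv`` with per-group mean/SEM; returns the row table.
    """
    df = pd.read_csv(path_in, sep="\t")
    for col in ("group", "w1", "w2", "w3", "w4"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path_in}")
    df["spt"] = [
        sucrose_preference(SucroseMeasurement(r.w1, r.w2, r.w3, r.w4))
        for r in df.itertuples()
    ]
    path_out = Path(path_out)
    df.to_csv(path_out, sep="\t", index=False)
    _summarise(df, "spt").to_csv(
        path_out.with_suffix(path_out.suffix + ".summary.tsv"), sep="\t", index=False
    )
    return df


def ddct_batch(path_in: str | Path, path_out: str | Path) -> pd.DataFrame:
    """Per-row 2^-ddCt from a TSV with columns group, ct_target_treated,
    ct_ref_treated, ct_target_control, ct_ref_control."""
    df = pd.read_csv(path_in, sep="\t")
    needed = ("group", "ct_target_treated", "ct_ref_treated",
              "ct_target_control", "ct_ref_control")
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path_in}")
    df["fold_change"] = [
        ddct_fold_change(QpcrQuad(r.ct_target_treated, r.ct_ref_treated,
                                  r.ct_target_control, r.ct_ref_control))
        for r in df.itertuples()
    ]
    path_out = Path(path_out)
    df.to_csv(path_out, sep="\t", index=False)
    _summarise(df, "fold_change").to_csv(
        path_out.with_suffix(path_out.suffix + ".summary.tsv"), sep="\t", index=False
    )
    return df
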