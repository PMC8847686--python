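"""Over-representation analysis with Benjamini-Hochberg FDR control.

Each annotation term is tested for enrichment of a query gene set against a
background universe with the hypergeometric upper tail
P[X >= k], X ~ Hypergeom(N, K, n), where N is the background size, K the
term size, n the query size and k the observed overlap. Terms with zero
overlap are excluded before correction by default (only representable terms
are tested), matching common ORA tool behaviour; pass
``test_zero_overlap=True`` to include them.

Multiple-testing correction is BH step-up, applied independently within each
term namespace (a namespace is the ``namespace|description`` prefix of the
GMT description field, mirroring per-ontology analyses; terms without a
prefix share the "default" namespace). A term is significant when its
q-value is below ``alpha`` (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AnnotationDB",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bh_fdr",
    "enrich",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationDB:
    """Annotation terms (id -> (description, members)) over a background set."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self):
        for tid, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {tid} has no members")
            extra = members - self.background
            if extra:
                raise ValueError(
                    f"term {tid} has {len(extra)} member(s) outside the background"
                )

    @staticmethod
    def namespace_of(description: str) -> str:
        return description.split("|", 1)[0] if "|" in description else "default"


@dataclass(frozen=True)
class EnrichmentResult:
    """One tested term: overlap counts, hypergeometric p, BH q, flag."""

    term_id: str
    description: str
    namespace: str
    k: int  # overlap
    K: int  # term size
    n: int  # effective query size
    N: int  # background size
    p_value: float
    q_value: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeom(N, K, n) (log-space via scipy's sf)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, got K={K} n={n} N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k} K={K} n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, clipped to
    [0, 1]; ties share ranks by sorted position.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    query,
    db: AnnotationDB,
    alpha: float = 0.05,
    test_zero_overlap: bool = False,
    background=None,
) -> list[EnrichmentResult]:
    """Test every annotation term for over-representation of the query.

    Query members outside the background are dropped with a warning; the
    effective query size n reflects the retained set. Results are sorted by
    (q, p, term_id) ascending. BH correction is applied within each term
    namespace independently.
    """
    bg = frozenset(background) if background is not None else db.background
    query = set(query)
    effective = query & bg
    dropped = query - effective
    if dropped:
        logger.warning(
            "%d/%d query identifier(s) outside the background were dropped",
            len(dropped), len(query),
        )
    if not effective:
        raise ValueError("no query identifier maps into the background")

    N = len(bg)
    n = len(effective)
    tested: list[tuple[str, str, str, int, int, float]] = []
    for tid in sorted(db.terms):
        desc, members = db.terms[tid]
        members_in_bg = members & bg
        if not members_in_bg:
            continue
        k = len(effective & members_in_bg)
        if k == 0 and not test_zero_overlap:
            continue
        K = len(members_in_bg)
        p = hypergeom_upper_tail(k, K, n, N)
        tested.append((tid, desc, AnnotationDB.namespace_of(desc), k, K, p))

    results: list[EnrichmentResult] = []
    namespaces = sorted({t[2] for t in tested})
    for ns in namespaces:
        group = [t for t in tested if t[2] == ns]
        qvals = bh_fdr([t[5] for t in group])
        for (tid, desc, _, k, K, p), q in zip(group, qvals):
            results.append(
                EnrichmentResult(
                    term_id=tid,
                    description=desc,
                    namespace=ns,
                    k=k, K=K, n=n, N=N,
                    p_value=p,
                    q_value=float(q),
                    significant=bool(q < alpha),
                )
            )
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]):
    """Tabulate results with columns matching the TSV output contract."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "description": r.description,
                "namespace": r.namespace,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "term_id", "description", "namespace", "k", "K", "n", "N",
            "p_value", "q_value", "significant",
        ],
    )
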