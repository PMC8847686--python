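# Planted-core demo: simulate a synthetic study and run the full screen.
#   netpharm run --config examples/demo.yaml --out demo_out
simulate:
  n_proteins: 500
  attachment_edges: 3
  core_size: 30
  core_density: 0.8
  n_drug_seeds: 40
  n_disease_seeds: 40
  seed_core_fraction: 0.8
  n_terms: 200
  term_size_range: [10, 30]
  n_enriched_terms: 5
  enrichment_strength: 0.9
  rng_seed: 7
screening:
  median_scope: intersection
enrichment:
  alpha: 0.05
ctpd:
  compound: paeoniflorin
  disease: MDD
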