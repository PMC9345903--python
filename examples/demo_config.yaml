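# Demo run: small synthetic cohort, all stages, deterministic at seed 42.
seed: 42
outdir: slscreen_out
simulate:
  n_tumor: 150
  n_normal: 30
  n_drivers: 4
  n_druggable: 20
  n_planted_pairs: 4
  n_ccl: 60
  n_extra_drugs: 5
thresholds:
  de_padj: 0.05
  coexpr_rho: 0.1
  coexpr_padj: 0.05
  fss: 0.45
  mutex_padj: 0.15   # 0.1 is the stricter documented alternative
  drug_p: 0.05
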