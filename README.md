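# tsmr — two-sample Mendelian randomization toolkit

`tsmr` runs a complete two-sample MR analysis from GWAS summary
statistics: instrument construction (genome-wide significance, MAF,
palindrome, LD-clumping and confounder-annotation filters), allele
harmonization, a full estimator battery (fixed/random/penalized/robust
IVW, maximum likelihood, simple and weighted medians, MR-Egger),
pleiotropy diagnostics (Cochran's Q, Egger intercept, MR-PRESSO,
leave-one-out, funnel data), multivariable MR, and closed-form power for
binary outcomes. A seeded synthetic-data module generates summary
statistics with known ground truth so every stage is testable offline.

## CLI

Every stage is a subcommand of `tsmr`; `tsmr run` chains them from a
YAML config.

```bash
# generate a synthetic dataset (121 SNPs, true OR 0.76 by default)
tsmr simulate --seed 7 --out-prefix sim

# instrument selection (p<5e-8, MAF>1%, palindrome MAF<.42, r2<.001 in 10Mb)
tsmr select-instruments sim_exposure.tsv --annotations ann.tsv \
    --out instruments.tsv --audit-out audit.json

# harmonize, estimate, diagnose
tsmr harmonize instruments.tsv sim_outcome.tsv --out harmonized.tsv
tsmr estimate harmonized.tsv --seed 1 --out estimates.json
tsmr diagnose harmonized.tsv --seed 1 --out pleiotropy.json

# multivariable MR and power
tsmr mvmr exposure.tsv outcome.tsv --covariate smoking.tsv
tsmr power --n 184305 --r2 0.02 --k 0.33 --odds-ratio 0.76

# whole pipeline from a config file
tsmr run config.yaml
```

Minimal `config.yaml`:

```yaml
exposure_path: sim_exposure.tsv
outcome_path: sim_outcome.tsv
annotations_path: ann.tsv      # optional
seed: 7
out_dir: reports
power:
  n: 184305
  r2: 0.02
  k: 0.33
  odds_ratio: 0.76
```

Input tables are TSV/CSV with a header; arbitrary source headers are
supported via column maps (`snp_id`, `chrom`, `pos`, `effect_allele`,
`other_allele`, `eaf`, `beta`, `se`, `pval`, `n`). Reports are JSON/TSV
and byte-identical across runs with the same seed.

## Library

```python
from tsmr import harmonize, ivw, egger, to_odds_ratio
from tsmr.synthetic_data import SimulationConfig, simulate_pair

exposure, outcome, truth = simulate_pair(SimulationConfig(seed=7))
h = harmonize(exposure, outcome)
print(to_odds_ratio(ivw(h, model="fixed")))
```

Modules map one-to-one onto the analysis stages: `summary_data`
(types + I/O), `instrument_selection`, `harmonization`,
`mr_estimators`, `pleiotropy_diagnostics`, `multivariable_mr`,
`power_calc`, `synthetic_data`, `cli`.

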