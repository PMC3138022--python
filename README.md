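# mcrscreen

Maximum Cumulative Ratio (MCR) screening for cumulative chemical risk in
water-monitoring data.

For each sample (treated as one individual's exposure to the mixture it
contains) the package computes the Hazard Quotient of every chemical
(dose / permitted dose), the Hazard Index (HI, the sum of HQs), the Maximum
Hazard Quotient (MHQ), the Maximum Cumulative Ratio (MCR = HI / MHQ, bounded
by 1 and the number of chemicals n) and the missed-toxicity fraction
(1 − 1/MCR) — the share of cumulative toxicity that a chemical-by-chemical
screening would not see.

Features:

* **Exposure scenario** — generic conservative drinking-water scenario
  (2 L/day, 60 kg adult, configurable) converting µg/L concentrations to
  mg/kg/day doses; a packaged chronic permitted-dose table of 81 pesticides
  and degradation products (chemicals without a permitted dose are excluded
  from the assessment with a logged warning).
* **Non-detect policies** — analytes below their detection limit (DL) are
  set to 0 (`case1_zero`) or DL/√2 (`case2_dl_sqrt2`); under case 1 the
  effective n is the number of detects, under case 2 the number of analytes.
* **Pipeline** — removal of samples with fewer than 5 detects, per-sample
  metrics per policy, HI classification at a cutoff (default 1), grouping by
  n with medians only for groups of ≥ 10 samples, and summary tables of
  min/max/mean HI and MCR overall and by HI class.
* **Statistics** — tie-corrected Kendall tau-b trend analyses (HI~n, MCR~n,
  MCR~HI per sample; HI~n, MCR~n on group medians) and a two-sample
  Wilcoxon/Mann-Whitney rank-sum comparison of MCR between HI classes
  (exact enumeration for small tie-free groups, tie-corrected normal
  approximation otherwise).
* **Synthetic data** — a seeded generator emulating large national survey
  structure (analyte panels clustered at 48/80 chemicals, ~9 detects per
  sample, lognormal detected concentrations, per-chemical detection
  limits, optional dominant chemical), plus equitoxic fixtures for exact
  closed-form checks.
* **CLI and I/O** — long/wide monitoring CSVs (USGS-style `<` remark code
  for non-detects), metrics/summary/statistics CSV outputs, diagnostic
  plots, plain-text run log.

## CLI

```sh
# generate a synthetic survey-like dataset (seed is mandatory)
mcr-screen simulate --seed 7 --n-samples 500 --out data.csv

# run the assessment under both non-detect policies
mcr-screen assess --input data.csv --out-dir out

# re-summarize and plot previously computed metrics
mcr-screen summarize --metrics out/metrics_case1_zero.csv
mcr-screen plot --metrics out/metrics_case1_zero.csv \
                --metrics out/metrics_case2_dl_sqrt2.csv --out-dir figs
```

`assess` writes, per policy, `metrics_<policy>.csv` (one row per sample:
hi, mhq, mcr, missed_fraction, n_detected, n_effective, top_chemical,
hi_class) and `groups_<policy>.csv`, plus `summary.csv`, `statistics.csv`
and `run.log`. The exposure scenario can be overridden with
`--ingestion-rate` / `--body-weight` or a `key = value` config file passed
via `--scenario-config`.

## Library

```python
from mcrscreen import (
    HQVector, individual_metrics, load_default_permitted_doses,
    compute_sample_metrics, NonDetectPolicy,
)

m = individual_metrics(HQVector.from_values([0.6, 0.8, 0.4, 0.5, 0.7]))
m.hi, m.mcr, m.missed_fraction   # 3.0, 3.75, 0.7333...
```

Undefined quantities (e.g. MCR when every HQ is zero) are represented by a
typed `UNDEFINED` marker that refuses arithmetic rather than silently
becoming a number.

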