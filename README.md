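# mirqpcr

A two-stage differential-expression pipeline for miRNA profiling on
TaqMan-style low-density qPCR arrays, built for the classic discovery →
validation design: a broad screen of ~667 miRNAs on array cards (e.g. 10
endometriosis vs 10 control endometrium samples), followed by targeted
re-measurement of a small candidate panel in technical triplicate on a
larger cohort.

The raw input is a table of cycle-threshold (Ct) values with explicit
non-detections ("Undetermined" wells, or Ct at/beyond the 40-cycle limit).
The pipeline implements:

- **Relative quantification (comparative Ct).** Within each sample,
  ΔCt = Ct(target) − Ct(endogenous control) (MammU6/RNU6B-style reference
  wells, averaged over detected wells); against a designated calibrator
  sample, ΔΔCt = ΔCt − ΔCt(calibrator) and RQ = 2^−ΔΔCt, assuming perfect
  per-cycle doubling. Non-detected wells propagate as missing — never
  imputed.
- **Detection/strength flags.** Per sample, detected assays are ranked by
  ΔCt; the strongest quartile is flagged *good*, the weakest *low*, the rest
  *normal*. Per assay and group this yields counts
  (*values*, *nd*, *good*, *normal*, *low*); only assays detected in ≥ 2
  samples of **both** groups are retained.
- **Discovery screen.** Per retained assay: group mean/SD/CV/max-min-ratio/
  median of RQ, the ratio of group means and medians expressed as *signed*
  fold-changes (r if r ≥ 1, else −1/r), and a two-sided Welch
  (unequal-variance) t-test. An assay is called differentially expressed
  when **any** of p ≤ 0.1, |mean FC| ≥ 2, or |median FC| ≥ 2 holds, and
  triaged into confidence tiers: *low* if any sample flagged it low, *top*
  if no low flags and at least one good flag in both groups, else *medium*.
- **Validation stage.** Replicate-aggregated RQ on the candidate panel,
  per-group median (min–max) summaries, and the two-sided
  Mann–Whitney–Wilcoxon test (exact for small tie-free groups, a
  moment-corrected normal approximation otherwise); significant when
  p < 0.05.
- **A Ct simulator.** Study-design-faithful synthetic data (assay baselines,
  per-sample loading shifts, planted group fold-changes, technical noise,
  endogenous-control wells, censoring at the detection limit) with a
  ground-truth table, so the entire pipeline is testable without instrument
  exports.

The transform/fit-shaped stages are scikit-learn estimators
(`DeltaCtTransformer`, `RelativeQuantityTransformer`,
`DifferentialExpressionScreen`, `MannWhitneyValidator`) and compose with
sklearn tooling; `run_screen` / `run_validation` drive the full stages from
raw Ct.

## Worked example

Simulate a discovery card with ten truly differential miRNAs (|fold-change|
= 4, both directions) among 667, then screen:

```python
from mirqpcr import SynthConfig, generate_dataset, run_screen

ds = generate_dataset(SynthConfig(n_assays=667, n_planted=10,
                                  planted_fold_changes=(4.0, -4.0), seed=42))
res = run_screen(ds.ct, ds.sheet, ds.panel,
                 case_group="endometriosis", control_group="control")
cols = ["assay", "mean_case", "mean_control", "mean_fc", "median_fc",
        "p_welch", "de_call", "tier"]
print(res.records[cols].head(5).round(3).to_string(index=False))
```

```
   assay  mean_case  mean_control  mean_fc  median_fc  p_welch  de_call tier
mir-0514      2.496         0.649    3.848      4.079    0.000     True  top
mir-0422      6.808         1.532    4.445      4.170    0.000     True  top
mir-0271      3.682         0.933    3.945      3.822    0.000     True  top
mir-0150      0.873         1.145   -1.312     -1.273    0.004     True  top
mir-0664      0.901         1.288   -1.430     -1.582    0.004     True  top
```

On this run all 667 assays pass retention, all 10 planted assays are called
DE (59 DE calls in total — the permissive union rule admits nulls by
design, which is what the confidence tiers and the validation stage are
for). `mean_fc` is the signed fold-change of group means: `mir-0514` is
≈ 3.8-fold *up* in the case group, `mir-0150` ≈ 1.3-fold *down*; `p_welch`
is the Welch t-test p-value, and `tier` the flag-based confidence triage.

The same run from a shell:

```sh
mirqpcr simulate --out demo --seed 42 --n-planted 10 \
    --fold-change 4 --fold-change -4
mirqpcr screen --ct demo/ct.csv --samples demo/samples.csv \
    --panel demo/panel.json --case-group endometriosis --out demo/screen.tsv
mirqpcr run-all --out demo_run --seed 42    # simulate + screen + validate
```

The bundled summary table of a published 15-miRNA candidate panel
illustrates the fold-change conventions on real numbers:

```python
from mirqpcr import load_discovery_panel_summary, signed_fold_change
row = load_discovery_panel_summary().set_index("mirna").loc["hsa-miR-145*"]
signed_fold_change(row["mean_endo"] / row["mean_ctrl"])   # -2.298 -> printed -2.3
```

## Layout

- `src/mirqpcr/data.py`, `io.py` — containers (CtMatrix / SampleSheet /
  PanelDef), readers/writers for long & wide Ct tables, sample sheets,
  panel JSON and the TSV reports.
- `src/mirqpcr/relquant.py` — replicate aggregation, ΔCt, ΔΔCt/RQ.
- `src/mirqpcr/flags.py` — quartile flags and the retention rule.
- `src/mirqpcr/screen.py` — discovery screen and confidence triage.
- `src/mirqpcr/validate.py` — Mann–Whitney validation stage.
- `src/mirqpcr/simulate.py` — the Ct simulator.
- `src/mirqpcr/pipeline.py`, `cli.py` — orchestrated runs with manifest and
  logs; `mirqpcr` CLI.
- `docs/methods.md` — model, conventions, numerical choices, limitations.
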