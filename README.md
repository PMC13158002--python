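# boldcsf

Global BOLD–CSF coupling analysis for resting-state fMRI: a tested,
reusable pipeline from 4D NIfTI volumes (real or synthetic) to per-subject
coupling metrics, a subject-shuffling permutation null, and cohort-level
group/correlation statistics — plus a seeded synthetic-cohort generator
with ground-truth bookkeeping for recovery tests.

The coupling metric is the lagged Pearson cross-correlation between the
grey-matter-mean ("gBOLD") signal and the mean CSF signal from the bottom
acquisition slice, evaluated over lags −10…+10 s. Negative lag means gBOLD
leads CSF; the per-subject headline statistic is the correlation at the
fixed +4 s lag, and a derivative-coupling curve (−d gBOLD/dt vs CSF) is
computed alongside.

## Layout

| module              | contents |
|---------------------|----------|
| `boldcsf.io`        | NIfTI volume/mask I/O, motion-parameter files (SPM rp dialect), volume discard, motion QC (1.5 mm / 1.5° strict-inequality rule) |
| `boldcsf.preproc`   | polynomial detrend, zero-phase 0.01–0.1 Hz Butterworth band-pass, 4 mm FWHM Gaussian smoothing, mask-mean extraction, z-scoring, the two-branch subject pipeline |
| `boldcsf.coupling`  | lagged cross-correlation (per-lag Pearson on the overlap segment), peak finding, coupling strength, derivative coupling, group-mean curves, derangement permutation null |
| `boldcsf.cohort`    | eligibility screening, chi-square / Mann-Whitney demographics, pooled two-sample t, covariate-adjusted OLS, Pearson clinical correlations with a Bonferroni α/m threshold |
| `boldcsf.simulate`  | synthetic cohort generator: narrowband gBOLD, CSF = delayed −d gBOLD/dt + calibrated noise, clinical tables, motion traces, NIfTI rendering |
| `boldcsf.cli`       | `boldcsf` command: `simulate`, `extract`, `couple`, `stats`, `run-all` |

## CLI

```sh
# generate a synthetic study (66 subjects by default), then run everything
boldcsf run-all --study-dir study --out-dir results --seed 1

# or stage by stage
boldcsf simulate --study-dir study --seed 1
boldcsf extract  --study-dir study --out-dir results
boldcsf couple   --study-dir study --out-dir results --n-iter 10000
boldcsf stats    --study-dir study --out-dir results
```

All stages accept `--config cfg.yaml` (YAML mirror of `boldcsf.cli.RunConfig`,
CLI flags take precedence). Outputs are plain TSV/JSON: per-subject series,
QC table with machine-readable exclusion reason codes, coupling curves and
metrics, group-mean curves, the permutation-null summary, demographics,
the adjusted model, and clinical correlations with Bonferroni flags.

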