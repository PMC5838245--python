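# seedconn

Seed-based intrinsic functional connectivity analysis of antidepressant
remission, with a synthetic cohort generator so that every stage is testable
offline.

The pipeline mirrors a task-residual ("intrinsic") connectivity design:

1. **QC / censoring** (`seedconn.qc`) — framewise displacement (rotations
   converted to arc length at 50 mm) and scaled whole-volume signal-change
   traces; volumes with FD ≥ 0.3 mm or intensity change > 10 are spikes, each
   censoring a 4-volume window (one before, two after); subjects with > 200
   of 600 volumes censored are excluded.
2. **Nuisance GLM + band-pass** (`seedconn.residuals`) — per-run design with
   HRF-convolved task regressors, the 24-column Volterra motion expansion
   (R, R², R₋₁, R₋₁²), white-matter/ventricle signals, one indicator per
   censored frame, and intercept + drift; OLS residuals are band-passed
   (0.009–0.08 Hz, zero-phase Butterworth) per run and concatenated.
3. **Seed connectivity** (`seedconn.connectivity`) — mean series over two
   bilateral 5-mm PCC spheres ([−11, −52, 37], [12, −52, 35]); voxel-wise
   Pearson correlation over retained frames, Fisher-z transformed.
4. **Group inference** (`seedconn.group`) — voxel-wise remitter-vs-non-remitter
   contrast with age/illness-duration/baseline-severity covariates (plus an
   optional drug × outcome interaction model); cluster-extent FWE correction
   by Freedman–Lane permutation of the maximum cluster extent; cluster value
   extraction, planned comparisons vs controls (Cohen's d from the adjusted
   contrast), paired pre/post tests, and summary-statistic t tests.
5. **Classification** (`seedconn.classify`) — remission labeling (week-8
   HRSD17 ≤ 7), venlafaxine-equivalent dosing, ROI mask = binary map ∩ 10-mm
   sphere, hierarchical logistic regression with likelihood-ratio and Wald
   tests, ROC/AUC, leave-one-out cross-validation (fold-internal
   standardization, no leakage), and specificity/added-value regressions.
6. **Synthetic cohorts** (`seedconn.synthetic`) — seeded generation of
   remitters / non-remitters / controls with band-limited latent signals,
   planted seed–target correlations per group (non-remitter hypo-connectivity,
   partial post-treatment attenuation), task-evoked responses, tissue
   nuisance signals, and motion spikes with matching intensity glitches.

## CLI

```bash
seedconn simulate --out data/ --seed 1 --n-remit 6 --n-nonremit 6 \
    --n-control 2 --n-runs 2 --volumes 80 --voxel-size 6.0 --sessions 1
seedconn run --root data/ --out results/          # qc → connectivity → group → classify
seedconn report --out results/
```

Individual stages (`qc`, `connectivity`, `group`, `classify`) accept the same
`--root/--out` plus `--config config.yaml` (see `seedconn.io.PipelineConfig`)
and `--seed`. Outputs include per-subject censoring reports, z-maps (NIfTI),
a cluster table (TSV), classification metrics (JSON), and a manifest
capturing every parameter and seed.

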