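# gaitstab

Estimation of the margin of stability (MoS) during walking from the
six-degree-of-freedom motion of the pelvis, implemented as a tested,
reusable pipeline:

1. **marker_io** — TRC/CSV (and hook-based C3D) marker trajectory reading
   and writing with canonical marker naming, unit conversion and gap fill.
2. **gait_geometry** — zero-phase low-pass filtering, CoM approximation from
   the pelvis marker triplet, pelvis rigid-body pose, trial-local gait
   frame, and heel-contact / toe-off detection.
3. **stability** — extrapolated centre of mass (XCoM), per-frame
   mediolateral and anterior margins against the support-toe base of
   support, and per-step critical values (minimum mediolateral margin,
   anterior margin at heel contact).
4. **pelvis_features** — per-step six-axis pelvic velocity profiles
   resampled to 0–50% of the gait cycle, laterality sign cancellation, and
   z-scored 306-column feature matrices.
5. **pma** — supervised principal motion analysis (a PLS1-style deflation
   regression): fit, prediction via literal loading projection or standard
   weight rotation, repeated five-fold cross-validation and component
   selection.
6. **gait_parameters** — per-step spatiotemporal parameters and
   score–parameter Pearson correlation tables with significance masking.
7. **synthetic_data** — an analytic walker emitting marker trajectories
   with exact ground truth (events, CoM path, independently evaluated
   margins) and a latent-factor generator for feature/target pairs.
8. **cli / pipeline** — YAML-configured end-to-end orchestration.

## Command-line usage

```bash
# synthetic fixtures
gaitstab synth walker --out demo --n-steps 10
gaitstab synth latent --out demo

# single-trial operations
gaitstab mos      --trial demo/walker.csv --events demo/walker_events.csv --out demo/mos.csv
gaitstab features --trial demo/walker.csv --out demo/features.csv
gaitstab cv       --features demo/features.csv --target ml --out demo/cv.csv

# full pipeline from a YAML config
gaitstab run --config cfg.yaml
```

Minimal configuration (unknown keys are rejected):

```yaml
synth: {kind: walker_batch, n_trials: 60, steps_per_trial: 10, seed: 1}
cv: {folds: 5, repeats: 5, a_max: 5, seed: 1}
channels: [six_axis, translational, angular]
output_dir: out
```

Real recordings are supplied via `inputs: ["trials/*.trc"]` (plus an
optional `*_events.csv` sidecar per trial when `events.source: sidecar`).
The report bundle contains per-step critical margins, the raw feature
matrix, cross-validation tables per target axis and channel subset, fitted
models, and score–parameter correlations.

## Conventions

Positions are metres in a right-handed ground frame with +z up.  The gait
frame is `(mediolateral, anterior, vertical)` with the mediolateral axis
`anterior × vertical` (to the walker's right) so the stacked axes have
determinant +1.  Margins are computed in metres and reported also in
centimetres.  Gravity defaults to 9.80665 m/s² and the pendulum length to
the trial-mean CoM height; both are configurable.
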