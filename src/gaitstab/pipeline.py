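"""End-to-end orchestration: markers -> margins -> features -> CV report.

The pipeline consumes a YAML configuration (schema below, unknown keys
rejected), processes every input trial through filtering, event detection,
margin-of-stability extraction and six-axis feature construction, then runs
the cross-validated principal-motion regression per target axis and channel
subset and writes plain-text reports.  Everything is deterministic given the
configured seed.
"""

from __future__ import annotations

import glob as globmod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, GaitStabError
from .gait_geometry import (
    compute_com,
    detect_events,
    filter_trial,
    gait_frame,
    provisional_frame,
    read_events_csv,
    toe_centre,
)
from .gait_parameters import compute_parameters, correlate_scores
from .marker_io import load_trial
from .pelvis_features import (
    CHANNEL_SUBSETS,
    assemble_features,
    feature_index,
    laterality_flip,
    resample_step,
    six_axis_velocity,
    stack_profiles,
    steps_from_events,
)
from .pma import cross_validate, fit, save_model
from .stability import G_DEFAULT, critical_mos, critical_table, mos_series
from .gait_geometry import pelvis_pose

_DEFAULTS = {
    "inputs": [],
    "synth": None,
    "marker_name_map": {},
    "y_up": False,
    "filter": {"cutoff_hz": 6.0, "order": 4},
    "events": {"source": "detect", "method": "relative_position",
               "sidecar_suffix": "_events.csv"},
    "cv": {"folds": 5, "repeats": 5, "a_max": 5, "seed": 0,
           "group_by_subject": False, "select_tol": 0.01,
           "projection": "paper", "standardize": "fold"},
    "channels": ["six_axis", "translational", "angular"],
    "gravity": G_DEFAULT,
    "edge_margin_s": 0.15,
    "steps_per_trial": None,
    "output_dir": "gaitstab_out",
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings (see ``_DEFAULTS`` for the schema)."""

    settings: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.settings[key]


def _merge(defaults, given, path=""):
    out = dict(defaults)
    for key, val in (given or {}).items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], dict) and defaults[key] and val is not None:
            if not isinstance(val, dict):
                raise ConfigError(f"{path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], val, path=f"{path}{key}.")
        else:
            out[key] = val
    return out


def validate_config(raw: dict) -> PipelineConfig:
    cfg = _merge(_DEFAULTS, raw or {})
    for ch in cfg["channels"]:
        if ch not in CHANNEL_SUBSETS:
            raise ConfigError(f"unknown channel subset {ch!r}")
    if cfg["events"]["source"] not in ("detect", "sidecar"):
        raise ConfigError("events.source must be 'detect' or 'sidecar'")
    return PipelineConfig(settings=cfg)


def load_config(path) -> PipelineConfig:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# trial processing


@dataclass
class TrialResult:
    trial_id: str
    subject_id: str
    steps: list
    criticals: pd.DataFrame
    profiles: list
    params: pd.DataFrame


def process_trial(trial, cfg: PipelineConfig, events=None) -> TrialResult:
    """Run a single trial through events, margins and features."""
    s = cfg.settings
    filtered = filter_trial(trial, s["filter"]["cutoff_hz"], s["filter"]["order"])
    com_f = compute_com(filtered)
    if events is None:
        prov = provisional_frame(compute_com(trial))
        events = detect_events(trial, prov, method=s["events"]["method"])
    frame = gait_frame(trial.times, com_f, events)
    toes = {side: toe_centre(filtered, side) for side in ("L", "R")}
    series = mos_series(trial.times, com_f, toes, events, frame, g=s["gravity"])
    margin = s["edge_margin_s"]
    steps = [st for st in steps_from_events(events)
             if st.t_start >= trial.times[0] + margin
             and st.t_end <= trial.times[-1] - margin]
    limit = s["steps_per_trial"] or (s["synth"] or {}).get("steps_per_trial")
    if limit:
        steps = steps[:limit]
    if not steps:
        raise GaitStabError(f"trial {trial.trial_id!r}: no usable steps")
    criticals = critical_table(critical_mos(series, steps))
    pose = pelvis_pose(filtered)
    vel6 = six_axis_velocity(pose, frame, trial.rate)
    profiles = [laterality_flip(resample_step(vel6, st, trial.rate), st) for st in steps]
    # raw markers for foot placements: zero-phase filtering rings at the
    # contact-instant corner and biases heel positions by several mm
    params = compute_parameters(trial, events, frame, com_f, steps=steps)
    subject_id = str(trial.subject_meta.get("subject_id", trial.trial_id))
    params["subject_id"] = subject_id
    params["subject_height"] = trial.subject_height or np.nan
    return TrialResult(trial_id=trial.trial_id, subject_id=subject_id, steps=steps,
                       criticals=criticals, profiles=profiles, params=params)


def _synth_walker_batch(synth_cfg: dict):
    """Generate a batch of walker trials with per-trial parameter variation."""
    from .synthetic_data import WalkerSpec, make_walker

    n_trials = int(synth_cfg.get("n_trials", 12))
    n_steps = int(synth_cfg.get("steps_per_trial", 10))
    seed = int(synth_cfg.get("seed", 0))
    rng = np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        spec = WalkerSpec(
            step_length=float(np.clip(rng.normal(0.63, 0.045), 0.4, 0.85)),
            step_width=float(np.clip(rng.normal(0.15, 0.03), 0.07, 0.25)),
            cadence=float(np.clip(rng.normal(118.0, 9.0), 90.0, 145.0)),
            com_height=float(np.clip(rng.normal(0.90, 0.05), 0.75, 1.05)),
            lateral_sway_amp=float(np.clip(rng.normal(0.020, 0.005), 0.005, 0.035)),
            vertical_bounce_amp=float(np.clip(rng.normal(0.015, 0.004), 0.004, 0.03)),
            pelvis_yaw_amp=float(np.clip(rng.normal(0.10, 0.03), 0.02, 0.2)),
            pelvis_roll_amp=float(np.clip(rng.normal(0.06, 0.02), 0.01, 0.15)),
            pelvis_pitch_amp=float(np.clip(rng.normal(0.04, 0.012), 0.01, 0.1)),
            heading=float(rng.uniform(0.0, 2.0 * np.pi)),
            n_steps=n_steps + 2,
            seed=seed + i,
        )
        trial, _ = make_walker(spec)
        trial.trial_id = f"walker_{i:03d}"
        trial.subject_meta["subject_id"] = f"S{i:03d}"
        trials.append(trial)
    return trials


def _iter_trials(cfg: PipelineConfig):
    s = cfg.settings
    if s["synth"]:
        kind = s["synth"].get("kind", "walker_batch")
        if kind != "walker_batch":
            raise ConfigError(f"unknown synth kind {kind!r}")
        yield from ((t, None) for t in _synth_walker_batch(s["synth"]))
        return
    paths = []
    for pattern in s["inputs"]:
        paths.extend(sorted(globmod.glob(str(pattern))))
    if not paths:
        raise ConfigError("no trials: input globs matched nothing and no synth block given")
    for p in paths:
        trial = load_trial(p, name_map=s["marker_name_map"], y_up=s["y_up"])
        events = None
        if s["events"]["source"] == "sidecar":
            side = Path(p).with_name(Path(p).stem + s["events"]["sidecar_suffix"])
            if not side.exists():
                raise ConfigError(f"missing events sidecar {side}")
            events = read_events_csv(side)
        yield trial, events


# ---------------------------------------------------------------------------
# full run


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the in-memory results (feature matrix, CV results per axis and
    channel subset, fitted models, correlation tables).
    """
    s = cfg.settings
    outdir = Path(s["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)

    results = []
    for trial, events in _iter_trials(cfg):
        try:
            results.append(process_trial(trial, cfg, events=events))
        except GaitStabError as exc:
            raise GaitStabError(f"trial {trial.trial_id!r}: {exc}") from exc
    if not results:
        raise ConfigError("no trials processed")

    crit_rows, param_rows, profiles = [], [], []
    for res in results:
        crit = res.criticals.copy()
        crit.insert(0, "trial_id", res.trial_id)
        crit.insert(1, "subject_id", res.subject_id)
        crit_rows.append(crit)
        param_rows.append(res.params)
        profiles.extend(res.profiles)
    criticals = pd.concat(crit_rows, ignore_index=True)
    params = pd.concat(param_rows, ignore_index=True)
    X_raw = stack_profiles(profiles)
    y = {"mediolateral": criticals["mos_ml_min"].to_numpy(),
         "anterior": criticals["mos_ap_hc"].to_numpy()}

    mos_out = criticals.rename(columns={
        "mos_ml_min": "mos_ml_min_m", "mos_ap_hc": "mos_ap_hc_m"})
    mos_out.to_csv(outdir / "mos_steps.csv", index=False, float_format="%.9g")

    feats = pd.DataFrame(X_raw, columns=feature_index())
    feats.insert(0, "step_id", criticals["step_id"].to_numpy())
    feats.insert(1, "subject_id", criticals["subject_id"].to_numpy())
    feats.insert(2, "mos_ml_min_m", y["mediolateral"])
    feats.insert(3, "mos_ap_hc_m", y["anterior"])
    feats.to_csv(outdir / "features.csv", index=False, float_format="%.9g")
    params.to_csv(outdir / "gait_parameters.csv", index=False, float_format="%.9g")

    cv_cfg = s["cv"]
    groups = criticals["subject_id"].to_numpy() if cv_cfg["group_by_subject"] else None
    cv_results, models, correlations = {}, {}, {}
    for axis in ("mediolateral", "anterior"):
        for subset in s["channels"]:
            sl = CHANNEL_SUBSETS[subset]
            cv = cross_validate(
                X_raw[:, sl], y[axis], a_max=cv_cfg["a_max"],
                n_folds=cv_cfg["folds"], n_repeats=cv_cfg["repeats"],
                seed=cv_cfg["seed"], projection=cv_cfg["projection"],
                standardize=cv_cfg["standardize"], select_tol=cv_cfg["select_tol"],
                groups=groups, y_kind=axis)
            cv_results[(axis, subset)] = cv
            cv.report().to_csv(outdir / f"cv_{axis}_{subset}.csv",
                               index=False, float_format="%.6g")
        # final model on all samples, six-axis channels, at the selected a
        chosen = cv_results[(axis, "six_axis")].chosen_a
        fm = assemble_features(profiles)
        model = fit(fm.X, y[axis], chosen, y_kind=axis, feature_stats=fm.stats)
        models[axis] = model
        save_model(model, outdir / f"model_{axis}.npz")
        heights = params["subject_height"].to_numpy() if params["subject_height"].notna().all() else None
        corr = correlate_scores(model.train_scores, params, height=heights)
        correlations[axis] = corr
        corr.masked.to_csv(outdir / f"correlations_{axis}.csv", float_format="%.4g")

    log = [
        f"gaitstab {__version__}",
        f"numpy {np.__version__}",
        f"seed {cv_cfg['seed']}",
        f"trials {len(results)}",
        f"steps {len(profiles)}",
        f"projection {cv_cfg['projection']}",
    ]
    for (axis, subset), cv in cv_results.items():
        log.append(f"chosen_a {axis}/{subset}: {cv.chosen_a}")
    (outdir / "run.log").write_text("\n".join(log) + "\n")

    return {"criticals": criticals, "params": params, "X_raw": X_raw, "y": y,
            "cv": cv_results, "models": models, "correlations": correlations,
            "output_dir": outdir}
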