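"""Reading and writing of 3-D marker trajectory files.

Two plain-text formats are supported natively:

* **TRC** -- the tab-separated format written by most optical motion-capture
  suites (``DataRate``/``Units`` header, one ``X/Y/Z`` column triplet per
  marker).
* **CSV** -- one ``<name>_x, <name>_y, <name>_z`` column triplet per marker
  with an optional YAML metadata sidecar (``<stem>.meta.yaml``) carrying the
  sampling rate, units and trial labels.

C3D files can be read through an injectable reader hook (see
:func:`load_trial`); no binary reader is bundled.

All positions are held internally in metres in a right-handed, ground-fixed
frame with the vertical (+z) axis opposed to gravity.  Files recorded y-up
are rotated at load time via ``y_up=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import MissingMarkerError, TrialFormatError

#: Canonical marker vocabulary.  SACR may be supplied directly or derived as
#: the midpoint of LPSIS/RPSIS.
CANONICAL_MARKERS = (
    "LASIS", "RASIS", "LPSIS", "RPSIS", "SACR",
    "LTOE2", "LTOE3", "RTOE2", "RTOE3", "LHEE", "RHEE",
)

#: Common vendor spellings mapped onto the canonical vocabulary.
MARKER_ALIASES = {
    "LASI": "LASIS", "RASI": "RASIS",
    "LPSI": "LPSIS", "RPSI": "RPSIS",
    "SACRUM": "SACR", "SACRAL": "SACR",
    "LHEEL": "LHEE", "RHEEL": "RHEE",
    "LMT2": "LTOE2", "LMT3": "LTOE3", "RMT2": "RTOE2", "RMT3": "RTOE3",
}

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}

#: Markers needed to run the full pipeline (SACR may come from the PSIS pair).
PELVIS_MARKERS = ("LASIS", "RASIS", "SACR")
FOOT_MARKERS = ("LTOE2", "LTOE3", "RTOE2", "RTOE3", "LHEE", "RHEE")


def canonical_name(name: str, name_map: dict | None = None) -> str:
    """Map a raw marker label onto the canonical vocabulary.

    The mapping is idempotent: canonical names map to themselves.
    """
    key = name.strip().upper()
    if name_map:
        upmap = {k.strip().upper(): v for k, v in name_map.items()}
        if key in upmap:
            return upmap[key]
    return MARKER_ALIASES.get(key, key)


@dataclass
class MarkerTrialSet:
    """Named 3-D marker trajectories with a common sampling rate.

    Attributes
    ----------
    markers : dict
        Canonical marker name -> ``(T, 3)`` position array in metres.
    rate : float
        Sampling frequency in Hz.
    trial_id : str
        Free-form trial label.
    subject_height : float or None
        Participant stature in metres, when known.
    subject_meta : dict
        Free-form subject metadata (id, mass, ...).
    """

    markers: dict
    rate: float
    trial_id: str = "trial"
    subject_height: float | None = None
    subject_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rate <= 0:
            raise TrialFormatError(f"sampling rate must be positive, got {self.rate}")
        lengths = {name: np.asarray(arr).shape for name, arr in self.markers.items()}
        for name, shape in lengths.items():
            if len(shape) != 2 or shape[1] != 3:
                raise TrialFormatError(f"marker {name!r} is not a T x 3 array (shape {shape})")
        n = {shape[0] for shape in lengths.values()}
        if len(n) > 1:
            raise TrialFormatError(f"inconsistent marker series lengths: {lengths}")
        if n and next(iter(n)) < 2:
            raise TrialFormatError("marker series must have at least 2 frames")
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, starting at zero."""
        return np.arange(self.n_frames) / self.rate

    def has(self, *names: str) -> bool:
        return all(n in self.markers for n in names)

    def require(self, *names: str) -> None:
        """Raise :class:`MissingMarkerError` listing absent markers."""
        missing = [n for n in names if n not in self.markers]
        if missing:
            raise MissingMarkerError(missing)

    def copy(self) -> "MarkerTrialSet":
        return MarkerTrialSet(
            markers={k: v.copy() for k, v in self.markers.items()},
            rate=self.rate,
            trial_id=self.trial_id,
            subject_height=self.subject_height,
            subject_meta=dict(self.subject_meta),
        )


def with_sacral_crest(trial: MarkerTrialSet) -> MarkerTrialSet:
    """Return a trial guaranteed to carry a SACR marker.

    If SACR is absent it is derived as the midpoint of the left and right
    posterior superior iliac spine markers.
    """
    if "SACR" in trial.markers:
        return trial
    trial.require("LPSIS", "RPSIS")
    out = trial.copy()
    out.markers["SACR"] = 0.5 * (trial.markers["LPSIS"] + trial.markers["RPSIS"])
    return out


def _fill_gaps(arr: np.ndarray, max_gap: int, name: str) -> np.ndarray:
    """Linearly interpolate NaN runs of at most ``max_gap`` frames."""
    if not np.isnan(arr).any():
        return arr
    out = arr.copy()
    t = np.arange(arr.shape[0])
    for c in range(arr.shape[1]):
        col = out[:, c]
        bad = np.isnan(col)
        if not bad.any():
            continue
        if bad.all() or bad[0] or bad[-1]:
            raise TrialFormatError(f"marker {name!r}: gap at series boundary cannot be filled")
        # longest run of consecutive NaNs
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0])))))
        if runs[::2].max(initial=0) > max_gap:
            raise TrialFormatError(
                f"marker {name!r}: gap longer than {max_gap} frames")
        out[:, c] = np.interp(t, t[~bad], col[~bad])
    return out


def _rotate_y_up(arr: np.ndarray) -> np.ndarray:
    # y-up -> z-up, proper rotation: (x, y, z) -> (x, -z, y)
    return np.column_stack([arr[:, 0], -arr[:, 2], arr[:, 1]])


def _finalize(raw: dict, rate: float, units: str, *, trial_id, subject_height,
              subject_meta, y_up: bool, name_map, max_gap: int) -> MarkerTrialSet:
    scale = _UNIT_SCALE.get(str(units).lower())
    if scale is None:
        raise TrialFormatError(f"unsupported units {units!r}")
    markers = {}
    for name, arr in raw.items():
        cname = canonical_name(name, name_map)
        arr = np.asarray(arr, dtype=float) * scale
        arr = _fill_gaps(arr, max_gap, cname)
        if y_up:
            arr = _rotate_y_up(arr)
        markers[cname] = arr
    trial = MarkerTrialSet(markers=markers, rate=float(rate), trial_id=trial_id,
                           subject_height=subject_height, subject_meta=subject_meta or {})
    if "SACR" not in trial.markers and trial.has("LPSIS", "RPSIS"):
        trial = with_sacral_crest(trial)
    return trial


# ---------------------------------------------------------------------------
# TRC


def _load_trc(path: Path):
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise TrialFormatError(f"{path}: truncated TRC file")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        units = header.get("Units", "mm")
    except (KeyError, ValueError) as exc:
        raise TrialFormatError(f"{path}: bad TRC header: {exc}") from exc
    names = [n for n in lines[3].split("\t")[2:] if n.strip()]
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        rows.append([float(v) if v.strip() else math.nan for v in line.split("\t")])
    width = 2 + 3 * len(names)
    data = np.full((len(rows), width), np.nan)
    for i, r in enumerate(rows):
        data[i, : min(len(r), width)] = r[:width]
    raw = {name: data[:, 2 + 3 * i: 5 + 3 * i] for i, name in enumerate(names)}
    return raw, rate, units


def _write_trc(trial: MarkerTrialSet, path: Path, units: str) -> None:
    scale = 1.0 / _UNIT_SCALE[units]
    names = list(trial.markers)
    n, rate = trial.n_frames, trial.rate
    head = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\t{units}\t{rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))),
        "",
    ]
    body = []
    times = trial.times
    stacked = np.hstack([trial.markers[nm] * scale for nm in names])
    for i in range(n):
        body.append(f"{i+1}\t{times[i]:.6f}\t" + "\t".join(f"{v:.12g}" for v in stacked[i]))
    path.write_text("\n".join(head + body) + "\n")


# ---------------------------------------------------------------------------
# CSV + YAML sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.yaml")


def _load_csv(path: Path, rate, units):
    import pandas as pd

    df = pd.read_csv(path)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    rate = rate if rate is not None else meta.get("rate")
    units = units if units is not None else meta.get("units", "m")
    if rate is None:
        raise TrialFormatError(f"{path}: sampling rate unknown (no sidecar, no rate argument)")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            names.append(col[:-2])
    raw = {}
    for name in names:
        cols = [f"{name}_x", f"{name}_y", f"{name}_z"]
        if not all(c in df.columns for c in cols):
            raise TrialFormatError(f"{path}: incomplete column triplet for marker {name!r}")
        raw[name] = df[cols].to_numpy(dtype=float)
    if not raw:
        raise TrialFormatError(f"{path}: no '<name>_x/_y/_z' column triplets found")
    return raw, float(rate), units, meta


def _write_csv(trial: MarkerTrialSet, path: Path, units: str) -> None:
    import pandas as pd

    scale = 1.0 / _UNIT_SCALE[units]
    cols = {}
    for name, arr in trial.markers.items():
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = arr[:, j] * scale
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    meta = {
        "rate": float(trial.rate),
        "units": units,
        "trial_id": trial.trial_id,
        "subject_height": trial.subject_height,
        "subject_meta": trial.subject_meta,
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


# ---------------------------------------------------------------------------
# public API


def load_trial(path, fmt: str | None = None, *, rate: float | None = None,
               units: str | None = None, y_up: bool = False,
               name_map: dict | None = None, required: tuple = (),
               max_gap: int = 10, c3d_reader=None) -> MarkerTrialSet:
    """Load a marker trial from ``path``.

    Parameters
    ----------
    fmt : {"trc", "csv", "c3d"}, optional
        Inferred from the file extension when omitted.
    rate, units :
        Override (or supply, for bare CSV files) the sampling rate and units.
    y_up : bool
        Rotate a y-up recording into the internal z-up frame.
    name_map : dict, optional
        Extra raw-name -> canonical-name substitutions.
    required : tuple of str
        Canonical markers that must be present after mapping.
    c3d_reader : callable, optional
        Hook ``f(path) -> (raw_dict, rate, units)`` used for ``fmt="c3d"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    meta = {}
    if fmt == "trc":
        raw, file_rate, file_units = _load_trc(path)
        rate = rate if rate is not None else file_rate
        units = units if units is not None else file_units
    elif fmt == "csv":
        raw, rate, units, meta = _load_csv(path, rate, units)
    elif fmt == "c3d":
        if c3d_reader is None:
            raise TrialFormatError(
                "C3D support requires a reader hook, e.g. "
                "load_trial(p, 'c3d', c3d_reader=my_ezc3d_adapter)")
        raw, file_rate, file_units = c3d_reader(path)
        rate = rate if rate is not None else file_rate
        units = units if units is not None else file_units
    else:
        raise TrialFormatError(f"unsupported format {fmt!r}")

    trial = _finalize(
        raw, rate, units or "m",
        trial_id=meta.get("trial_id", path.stem),
        subject_height=meta.get("subject_height"),
        subject_meta=meta.get("subject_meta") or {},
        y_up=y_up, name_map=name_map, max_gap=max_gap,
    )
    if required:
        trial.require(*required)
    return trial


def write_trial(trial: MarkerTrialSet, path, fmt: str | None = None,
                units: str = "m") -> None:
    """Write a trial to TRC or CSV (with YAML sidecar)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if units not in _UNIT_SCALE:
        raise TrialFormatError(f"unsupported units {units!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "trc":
        _write_trc(trial, path, units)
    elif fmt == "csv":
        _write_csv(trial, path, units)
    else:
        raise TrialFormatError(f"unsupported format {fmt!r}")
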