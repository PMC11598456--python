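"""Supervised principal motion analysis (a PLS1-style deflation regression).

The fit iterates, for components ``n = 1..a`` on the deflated matrices
``X_n`` and targets ``y_n`` (``X_1 = X``, ``y_1 = y`` centred)::

    s_n = X_n X_n^T y_n / ||X_n^T y_n||        (scores)
    p_n = X_n^T s_n / (s_n^T s_n)              (loadings)
    q_n = y^T s_n / (s_n^T s_n)                (coefficient, undeflated y)
    X_{n+1} = X_n - s_n p_n^T
    y_{n+1} = y_n - q_n s_n

Training predictions are ``sum_n q_n s_n``; test scores are obtained by a
single projection of the (standardized, undeflated) test rows onto the
loadings, ``s_n = X_test p_n``.  That literal projection is the default; the
standard PLS weight rotation ``R = W (P^T W)^{-1}``, which reproduces the
training map exactly on noiseless data, is available as
``projection="pls_rotation"``.

The target vector is centred internally and the mean restored at prediction
time; the published equations carry no intercept, which would bias every
prediction by the mean target value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GaitStabError, RankExhaustedError
from .pelvis_features import FeatureStats

PROJECTIONS = ("paper", "pls_rotation")


@dataclass
class PMAModel:
    """Fitted principal-motion regression."""

    a: int
    loadings: np.ndarray        # (a, n_features)  p_n
    weights: np.ndarray         # (a, n_features)  w_n, for the rotation projection
    coeffs: np.ndarray          # (a,)             q_n
    train_scores: np.ndarray    # (k, a)           s_n
    y_mean: float
    y_kind: str = "mediolateral"
    feature_stats: FeatureStats | None = None

    @property
    def n_features(self) -> int:
        return self.loadings.shape[1]


def fit(X: np.ndarray, y: np.ndarray, a: int, *, y_kind: str = "mediolateral",
        feature_stats: FeatureStats | None = None, tol: float = 1e-12) -> PMAModel:
    """Fit ``a`` principal motions to a standardized ``(k, m)`` matrix.

    Raises :class:`RankExhaustedError` (reporting the achievable count) when
    the deflated cross-covariance vanishes before ``a`` components, except in
    the guarded all-zero-target case which yields a zero model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise GaitStabError(f"X {X.shape} and y {y.shape} are inconsistent")
    if a < 1:
        raise GaitStabError("number of principal motions must be >= 1")
    k, m = X.shape
    y_mean = float(y.mean())
    yc = y - y_mean

    P = np.zeros((a, m))
    W = np.zeros((a, m))
    q = np.zeros(a)
    S = np.zeros((k, a))

    if np.allclose(yc, 0.0):
        # guarded degenerate fit: predicts the constant mean
        return PMAModel(a=a, loadings=P, weights=W, coeffs=q, train_scores=S,
                        y_mean=y_mean, y_kind=y_kind, feature_stats=feature_stats)

    Xn = X.copy()
    yn = yc.copy()
    scale = np.linalg.norm(X) * np.linalg.norm(yc)
    for n in range(a):
        w = Xn.T @ yn
        nw = np.linalg.norm(w)
        if nw <= tol * max(scale, 1.0):
            raise RankExhaustedError(achieved=n, requested=a)
        w /= nw
        s = Xn @ w
        ss = s @ s
        if ss <= tol:
            raise RankExhaustedError(achieved=n, requested=a)
        p = Xn.T @ s / ss
        qn = (yc @ s) / ss
        W[n], P[n], q[n], S[:, n] = w, p, qn, s
        Xn = Xn - np.outer(s, p)
        yn = yn - qn * s
    return PMAModel(a=a, loadings=P, weights=W, coeffs=q, train_scores=S,
                    y_mean=y_mean, y_kind=y_kind, feature_stats=feature_stats)


def _rotation(model: PMAModel, a: int) -> np.ndarray:
    """PLS weight rotation for the leading ``a`` components: columns r_n such
    that X_test @ R reproduces the training score map."""
    Wm = model.weights[:a].T
    Pm = model.loadings[:a].T
    return Wm @ np.linalg.inv(Pm.T @ Wm)


def test_scores(model: PMAModel, X_new: np.ndarray, projection: str = "paper",
                a: int | None = None) -> np.ndarray:
    """Scores of new (standardized) rows under either projection rule."""
    X_new = np.asarray(X_new, dtype=float)
    a = model.a if a is None else a
    if not 1 <= a <= model.a:
        raise GaitStabError(f"a={a} outside fitted range 1..{model.a}")
    if X_new.ndim != 2 or X_new.shape[1] != model.n_features:
        raise GaitStabError(
            f"feature count mismatch: got {X_new.shape}, model has {model.n_features} features")
    if projection == "paper":
        return X_new @ model.loadings[:a].T
    if projection == "pls_rotation":
        return X_new @ _rotation(model, a)
    raise GaitStabError(f"unknown projection {projection!r} (use one of {PROJECTIONS})")


def predict(model: PMAModel, X_new: np.ndarray, projection: str = "paper",
            a: int | None = None) -> np.ndarray:
    """Predict targets for standardized rows: ``y_mean + sum_n q_n s_n``."""
    a = model.a if a is None else a
    s = test_scores(model, X_new, projection=projection, a=a)
    return model.y_mean + s @ model.coeffs[:a]


def fitted_values(model: PMAModel, a: int | None = None) -> np.ndarray:
    """Training reconstruction from the stored scores."""
    a = model.a if a is None else a
    return model.y_mean + model.train_scores[:, :a] @ model.coeffs[:a]


def regression_equation(model: PMAModel) -> np.ndarray:
    """Ordered score coefficients (q_1, ..., q_a) for reporting."""
    return model.coeffs.copy()


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Five-fold cross-validation summary over ``a = 1..a_max``."""

    a_values: np.ndarray
    r_mean: np.ndarray          # Pearson r, mean over repeats
    r_sd: np.ndarray
    rmse: np.ndarray            # pooled per repeat, averaged over repeats (y units)
    chosen_a: int
    r_per_repeat: np.ndarray    # (repeats, a_max)
    rmse_per_repeat: np.ndarray
    folds: list = field(default_factory=list)   # per repeat: fold id per sample
    seed: int = 0
    projection: str = "paper"
    n_samples: int = 0

    def report(self):
        """Tabular view mirroring a per-``a`` accuracy table."""
        import pandas as pd

        return pd.DataFrame({
            "a": self.a_values,
            "r_mean": self.r_mean,
            "r_sd": self.r_sd,
            "rmse": self.rmse,
            "rmse_cm": 100.0 * self.rmse,
        })


def _make_folds(rng, n, n_folds, groups=None):
    """Fold id per sample; whole groups are kept together when given."""
    fold_of = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_of[chunk] = f
    else:
        groups = np.asarray(groups)
        uniq = rng.permutation(np.unique(groups))
        gfold = {g: f for f, gs in enumerate(np.array_split(uniq, n_folds)) for g in gs}
        for i, g in enumerate(groups):
            fold_of[i] = gfold[g]
    return fold_of


def cross_validate(X_raw: np.ndarray, y: np.ndarray, a_max: int = 5, *,
                   n_folds: int = 5, n_repeats: int = 5, seed: int = 0,
                   projection: str = "paper", standardize: str = "fold",
                   select_tol: float = 0.01, groups=None,
                   y_kind: str = "mediolateral") -> CVResult:
    """Repeated random five-fold cross-validation with component selection.

    Parameters
    ----------
    X_raw : (k, m)
        Unstandardized feature matrix.  With ``standardize="fold"`` (default)
        each training fold fits its own column statistics which are applied
        to the held-out fold; ``"global"`` z-scores once on all samples (the
        leaking variant); ``"none"`` uses the matrix as given.
    select_tol : float
        The chosen ``a`` is the smallest whose repeat-averaged pooled RMSE is
        within ``select_tol`` (relative) of the minimum.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    k = X_raw.shape[0]
    if k < n_folds:
        raise GaitStabError(f"{k} samples cannot fill {n_folds} folds")
    if standardize not in ("fold", "global", "none"):
        raise GaitStabError(f"unknown standardize mode {standardize!r}")
    if standardize == "global":
        from .pelvis_features import apply_stats, fit_stats
        X_raw = apply_stats(X_raw, fit_stats(X_raw, labels=[str(i) for i in range(X_raw.shape[1])]))
        standardize = "none"

    rng = np.random.default_rng(seed)
    r_rep = np.full((n_repeats, a_max), np.nan)
    rmse_rep = np.full((n_repeats, a_max), np.nan)
    folds_out = []
    for rep in range(n_repeats):
        fold_of = _make_folds(rng, k, n_folds, groups)
        folds_out.append(fold_of)
        preds = np.zeros((a_max, k))
        for f in range(n_folds):
            test = fold_of == f
            train = ~test
            if test.sum() < 1 or train.sum() < 2:
                raise GaitStabError(f"fold {f} too small")
            Xtr, Xte = X_raw[train], X_raw[test]
            if standardize == "fold":
                from .pelvis_features import apply_stats, fit_stats
                stats = fit_stats(Xtr, labels=[str(i) for i in range(Xtr.shape[1])])
                Xtr, Xte = apply_stats(Xtr, stats), apply_stats(Xte, stats)
            try:
                model = fit(Xtr, y[train], a_max, y_kind=y_kind)
                a_eff = a_max
            except RankExhaustedError as exc:
                if exc.achieved < 1:
                    raise
                model = fit(Xtr, y[train], exc.achieved, y_kind=y_kind)
                a_eff = exc.achieved
            for a in range(1, a_max + 1):
                preds[a - 1, test] = predict(model, Xte, projection=projection,
                                             a=min(a, a_eff))
        for a in range(1, a_max + 1):
            p = preds[a - 1]
            rmse_rep[rep, a - 1] = np.sqrt(np.mean((p - y) ** 2))
            r_rep[rep, a - 1] = np.corrcoef(p, y)[0, 1] if np.std(p) > 0 else 0.0

    rmse = rmse_rep.mean(axis=0)
    best = rmse.min()
    chosen = int(np.flatnonzero(rmse <= (1.0 + select_tol) * best)[0]) + 1
    return CVResult(
        a_values=np.arange(1, a_max + 1),
        r_mean=r_rep.mean(axis=0), r_sd=r_rep.std(axis=0, ddof=1) if n_repeats > 1 else np.zeros(a_max),
        rmse=rmse, chosen_a=chosen,
        r_per_repeat=r_rep, rmse_per_repeat=rmse_rep,
        folds=folds_out, seed=seed, projection=projection, n_samples=k,
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model: PMAModel, path) -> None:
    """Store a fitted model as a flat NPZ container."""
    extra = {}
    if model.feature_stats is not None:
        extra = {"stats_mean": model.feature_stats.mean, "stats_sd": model.feature_stats.sd}
    np.savez(path, a=model.a, loadings=model.loadings, weights=model.weights,
             coeffs=model.coeffs, train_scores=model.train_scores,
             y_mean=model.y_mean, y_kind=model.y_kind, **extra)


def load_model(path) -> PMAModel:
    with np.load(path, allow_pickle=False) as z:
        stats = None
        if "stats_mean" in z:
            stats = FeatureStats(mean=z["stats_mean"], sd=z["stats_sd"])
        return PMAModel(a=int(z["a"]), loadings=z["loadings"], weights=z["weights"],
                        coeffs=z["coeffs"], train_scores=z["train_scores"],
                        y_mean=float(z["y_mean"]), y_kind=str(z["y_kind"]),
                        feature_stats=stats)
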