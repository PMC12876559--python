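"""Gaussian-process regression from shape coefficients to loss coefficients.

Two independent GP regressors map the shape-coefficient vector alpha to Kv
and Kt.  The composite kernel is

    k(x, x') = C * k_base(x, x') + k_white(x, x'),

with k_base an anisotropic RBF or Matern kernel (per-dimension length
scales, each initialised to 1 and bounded to [1e-3, 1e5]) and a White
kernel contributing sigma^2 only on the training diagonal.  Features may be
enriched with second- or third-order monomials of alpha, and targets may be
log-transformed, y = ln(K + eps), eps = 1e-6, to tame skewness.  Kernel
hyperparameters are refined by maximising the log marginal likelihood
(multi-start L-BFGS-B within bounds); the discrete choices (degree, log
transform, kernel family, nu) plus C and sigma^2 starting values are chosen
by a seeded hyperparameter search (TPE-style or pure random) minimising the
mean 5-fold cross-validation MSE on the transformed target scale.

Predictions on the original scale use the log-normal back-transform:
mean = exp(mu + s^2/2) - eps and the log-normal standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (RBF, ConstantKernel, Matern,
                                              WhiteKernel)
from sklearn.model_selection import KFold

from .constants import StateError

#: Search-space bounds (log10) for the constant factor and the noise level.
C_BOUNDS = (1e-1, 1e5)
NOISE_BOUNDS = (1e-6, 1e1)
LENGTH_SCALE_BOUNDS = (1e-3, 1e5)
LOG_OFFSET = 1e-6


@dataclass(frozen=True)
class KernelConfig:
    """Composite-kernel configuration (family, smoothness, scales)."""

    family: str = "RBF"
    nu: float | None = None
    c_scale: float = 1.0
    noise_var: float = 1e-5
    length_scales: np.ndarray | None = None
    c_bounds: tuple[float, float] = C_BOUNDS
    noise_bounds: tuple[float, float] = NOISE_BOUNDS
    length_scale_bounds: tuple[float, float] = LENGTH_SCALE_BOUNDS

    def __post_init__(self) -> None:
        if self.family not in ("RBF", "Matern"):
            raise ValueError("family must be 'RBF' or 'Matern'")
        if (self.family == "Matern") != (self.nu is not None):
            raise ValueError("nu must be given iff family == 'Matern'")
        if self.nu is not None and self.nu not in (0.5, 1.5, 2.5):
            raise ValueError("nu must be one of 0.5, 1.5, 2.5")


@dataclass(frozen=True)
class FeatureTransform:
    """Feature enrichment and target transform applied around the GP."""

    degree: int = 1
    log_target: bool = False
    log_offset: float = LOG_OFFSET
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")

    def transform_target(self, y: np.ndarray) -> np.ndarray:
        return np.log(y + self.log_offset) if self.log_target else np.asarray(y, float)

    def inverse_target(self, y: np.ndarray) -> np.ndarray:
        return np.exp(y) - self.log_offset if self.log_target else np.asarray(y, float)


def polynomial_enrich(alpha: np.ndarray, degree: int) -> np.ndarray:
    """Monomial enrichment of a coefficient vector (or of feature rows).

    Deterministic feature order: the linear terms, then for degree >= 2 all
    squares alpha_i^2 followed by the pairwise interactions alpha_i alpha_j
    (i < j), then for degree 3 all total-degree-3 monomials in
    lexicographic index order (i <= j <= k).
    """
    a = np.asarray(alpha, dtype=float)
    single = a.ndim == 1
    X = np.atleast_2d(a)
    d = X.shape[1]
    if d == 0:
        raise ValueError("alpha must be non-empty")
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    blocks = [X]
    if degree >= 2:
        blocks.append(X ** 2)
        blocks.append(np.stack([X[:, i] * X[:, j]
                                for i, j in combinations_with_replacement(range(d), 2)
                                if i < j], axis=1) if d > 1
                      else np.empty((X.shape[0], 0)))
    if degree >= 3:
        blocks.append(np.stack([X[:, i] * X[:, j] * X[:, k]
                                for i, j, k in
                                combinations_with_replacement(range(d), 3)],
                               axis=1))
    out = np.hstack(blocks)
    return out[0] if single else out


def build_kernel(cfg: KernelConfig, ndim: int):
    """Assemble the sklearn composite kernel for ``ndim`` features."""
    ls = (np.ones(ndim) if cfg.length_scales is None
          else np.asarray(cfg.length_scales, dtype=float))
    if ls.size != ndim:
        raise ValueError("length_scales length must equal the feature "
                         "dimension")
    if cfg.family == "RBF":
        base = RBF(length_scale=ls, length_scale_bounds=cfg.length_scale_bounds)
    else:
        base = Matern(length_scale=ls, nu=cfg.nu,
                      length_scale_bounds=cfg.length_scale_bounds)
    return (ConstantKernel(cfg.c_scale, constant_value_bounds=cfg.c_bounds)
            * base
            + WhiteKernel(cfg.noise_var, noise_level_bounds=cfg.noise_bounds))


def kernel_eval(cfg: KernelConfig, X: np.ndarray,
                X2: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the composite kernel.

    With ``X2 is None`` this is the training kernel and the White term
    appears on the diagonal; a cross-covariance evaluation never receives
    the White contribution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = build_kernel(cfg, X.shape[1])
    if X2 is None:
        return k(X)
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X2.shape[1] != X.shape[1]:
        raise ValueError("feature dimensions of X and X2 differ")
    return k(X, X2)


@dataclass(frozen=True)
class GPRModel:
    """A trained GP regressor plus its feature/target transforms."""

    kernel: KernelConfig
    transform: FeatureTransform
    target_name: str
    gpr: GaussianProcessRegressor | None = None
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    X_train: np.ndarray | None = None
    y_train: np.ndarray | None = None

    @property
    def trained(self) -> bool:
        return self.gpr is not None

    def features(self, alpha_rows: np.ndarray) -> np.ndarray:
        """Enriched, standardized feature rows for raw alpha rows."""
        Z = polynomial_enrich(np.atleast_2d(alpha_rows), self.transform.degree)
        if self.transform.standardize:
            Z = (Z - self.x_mean) / self.x_scale
        return Z


def gpr_fit(X: np.ndarray, y: np.ndarray, cfg: KernelConfig,
            transform: FeatureTransform, seed: int = 0,
            n_restarts: int = 3, target_name: str = "") -> GPRModel:
    """Fit one GP regressor on raw alpha rows ``X`` and targets ``y``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("at least 2 training rows are required")
    if transform.log_target and np.any(y + transform.log_offset <= 0):
        raise ValueError("log transform requires y + offset > 0")
    Z = polynomial_enrich(X, transform.degree)
    x_mean = Z.mean(axis=0)
    x_scale = Z.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    if transform.standardize:
        Z = (Z - x_mean) / x_scale
    yt = transform.transform_target(y)
    kernel = build_kernel(cfg, Z.shape[1])
    gpr = GaussianProcessRegressor(kernel=kernel, alpha=0.0,
                                   normalize_y=False,
                                   n_restarts_optimizer=n_restarts,
                                   random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(Z, yt)
    return GPRModel(kernel=cfg, transform=transform, target_name=target_name,
                    gpr=gpr, x_mean=x_mean, x_scale=x_scale,
                    X_train=X, y_train=y)


def gpr_predict(model: GPRModel, X: np.ndarray,
                transformed_scale: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and predictive standard deviation for alpha rows.

    Results are reported on the original target scale unless
    ``transformed_scale`` is set (used by the cross-validation objective).
    When the log transform is active the original-scale mean and sd are the
    exact log-normal moments of the latent Gaussian posterior.
    """
    if not model.trained:
        raise StateError("gpr_predict requires a trained model")
    Z = model.features(np.atleast_2d(np.asarray(X, dtype=float)))
    mu, sd = model.gpr.predict(Z, return_std=True)
    if transformed_scale or not model.transform.log_target:
        return mu, sd
    var = sd ** 2
    mean = np.exp(mu + 0.5 * var) - model.transform.log_offset
    sd_orig = np.sqrt(np.expm1(var) * np.exp(2.0 * mu + var))
    return mean, sd_orig


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.mean((y_true - y_pred) ** 2))


def cv_mse(X: np.ndarray, y: np.ndarray, cfg: KernelConfig,
           transform: FeatureTransform, k: int = 5, seed: int = 0,
           n_restarts: int = 1) -> float:
    """Mean k-fold cross-validation MSE on the transformed target scale."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of rows")
    if transform.log_target and np.any(y + transform.log_offset <= 0):
        raise ValueError("log transform requires positive targets")
    scores = []
    for train_idx, val_idx in KFold(n_splits=k, shuffle=True,
                                    random_state=seed).split(X):
        model = gpr_fit(X[train_idx], y[train_idx], cfg, transform,
                        seed=seed, n_restarts=n_restarts)
        mu, _ = gpr_predict(model, X[val_idx], transformed_scale=True)
        scores.append(mse(transform.transform_target(y[val_idx]), mu))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Hyperparameter search (seeded TPE-style sampler with a random fallback)


@dataclass(frozen=True)
class TrialRecord:
    """One evaluated hyperparameter configuration."""

    index: int
    params: dict
    cv_mse: float
    seed: int

    def __post_init__(self) -> None:
        if not self.cv_mse >= 0:
            raise ValueError("cv_mse must be non-negative")


_CATEGORICAL_SPACE = {
    "degree": (1, 2, 3),
    "log_target": (False, True),
    "family": ("Matern", "RBF"),
    "nu": (0.5, 1.5, 2.5),          # only when family == Matern
}
_LOG_UNIFORM_SPACE = {               # log10 bounds
    "c_scale": (math.log10(C_BOUNDS[0]), math.log10(C_BOUNDS[1])),
    "noise_var": (math.log10(NOISE_BOUNDS[0]), math.log10(NOISE_BOUNDS[1])),
}
_N_STARTUP = 10       # random trials before the TPE proposal kicks in
_GAMMA = 0.25         # fraction of trials considered "good"
_N_CANDIDATES = 24    # candidates scored per parameter proposal


def _random_params(rng: np.random.Generator) -> dict:
    p = {
        "degree": int(rng.choice(_CATEGORICAL_SPACE["degree"])),
        "log_target": bool(rng.choice(_CATEGORICAL_SPACE["log_target"])),
        "family": str(rng.choice(_CATEGORICAL_SPACE["family"])),
    }
    p["nu"] = (float(rng.choice(_CATEGORICAL_SPACE["nu"]))
               if p["family"] == "Matern" else None)
    for name, (lo, hi) in _LOG_UNIFORM_SPACE.items():
        p[name] = float(10.0 ** rng.uniform(lo, hi))
    return p


def _tpe_params(history: list[TrialRecord], rng: np.random.Generator) -> dict:
    """Propose a configuration by the density-ratio heuristic.

    Trials are split into a good set (best ceil(gamma*n)) and the rest; each
    parameter is proposed independently by drawing candidates from the
    good-set density and keeping the candidate with the largest l/g ratio
    (smoothed counts for categoricals, Gaussian mixtures in log10 space for
    the continuous parameters).
    """
    ordered = sorted(history, key=lambda t: t.cv_mse)
    n_good = max(1, math.ceil(_GAMMA * len(ordered)))
    good, bad = ordered[:n_good], ordered[n_good:]

    def cat_choice(name: str, values: tuple, records) -> dict:
        counts = {v: 1.0 for v in values}  # +1 smoothing
        for t in records:
            v = t.params.get(name)
            if v in counts:
                counts[v] += 1.0
        total = sum(counts.values())
        return {v: c / total for v, c in counts.items()}

    p: dict = {}
    for name, values in (("degree", _CATEGORICAL_SPACE["degree"]),
                         ("log_target", _CATEGORICAL_SPACE["log_target"]),
                         ("family", _CATEGORICAL_SPACE["family"])):
        l = cat_choice(name, values, good)
        g = cat_choice(name, values, bad)
        cands = rng.choice(len(values), size=_N_CANDIDATES,
                           p=[l[v] for v in values])
        best = max(set(cands.tolist()),
                   key=lambda i: l[values[i]] / g[values[i]])
        p[name] = values[best]
    p["degree"] = int(p["degree"])
    p["log_target"] = bool(p["log_target"])
    if p["family"] == "Matern":
        values = _CATEGORICAL_SPACE["nu"]
        recs_good = [t for t in good if t.params.get("nu") is not None]
        recs_bad = [t for t in bad if t.params.get("nu") is not None]
        l = cat_choice("nu", values, recs_good)
        g = cat_choice("nu", values, recs_bad)
        cands = rng.choice(len(values), size=_N_CANDIDATES,
                           p=[l[v] for v in values])
        best = max(set(cands.tolist()),
                   key=lambda i: l[values[i]] / g[values[i]])
        p["nu"] = float(values[best])
    else:
        p["nu"] = None

    def mixture_logpdf(x: float, centers: np.ndarray, lo: float,
                       hi: float) -> float:
        if centers.size == 0:
            return -math.log(hi - lo)
        bw = max((hi - lo) / (2.0 * math.sqrt(centers.size)), 1e-3)
        z = (x - centers) / bw
        dens = np.exp(-0.5 * z * z).sum() / (centers.size * bw *
                                             math.sqrt(2 * math.pi))
        # uniform prior component keeps g bounded away from zero
        dens = 0.75 * dens + 0.25 / (hi - lo)
        return math.log(dens)

    for name, (lo, hi) in _LOG_UNIFORM_SPACE.items():
        cg = np.array([math.log10(t.params[name]) for t in good])
        cb = np.array([math.log10(t.params[name]) for t in bad])
        bw = max((hi - lo) / (2.0 * math.sqrt(max(cg.size, 1))), 1e-3)
        if cg.size:
            cands = rng.normal(cg[rng.integers(cg.size, size=_N_CANDIDATES)],
                               bw)
        else:
            cands = rng.uniform(lo, hi, size=_N_CANDIDATES)
        cands = np.clip(cands, lo, hi)
        scores = [mixture_logpdf(x, cg, lo, hi) - mixture_logpdf(x, cb, lo, hi)
                  for x in cands]
        p[name] = float(10.0 ** cands[int(np.argmax(scores))])
    return p


def _params_to_config(p: dict) -> tuple[KernelConfig, FeatureTransform]:
    cfg = KernelConfig(family=p["family"], nu=p["nu"], c_scale=p["c_scale"],
                       noise_var=p["noise_var"])
    tr = FeatureTransform(degree=p["degree"], log_target=p["log_target"])
    return cfg, tr


def hyperparameter_search(X: np.ndarray, y: np.ndarray, n_trials: int = 20,
                          k: int = 5, seed: int = 0, sampler: str = "tpe"
                          ) -> tuple[dict, list[TrialRecord]]:
    """Search the hyperparameter space, minimising the mean k-fold CV MSE.

    Returns the best parameter dictionary and the full trial history.
    Fully deterministic for a fixed seed.
    """
    if sampler not in ("tpe", "random"):
        raise ValueError("sampler must be 'tpe' or 'random'")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of rows")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E5]))
    history: list[TrialRecord] = []
    for i in range(n_trials):
        if sampler == "tpe" and len(history) >= _N_STARTUP:
            params = _tpe_params(history, rng)
        else:
            params = _random_params(rng)
        cfg, tr = _params_to_config(params)
        try:
            score = cv_mse(X, y, cfg, tr, k=k, seed=seed)
        except (ValueError, np.linalg.LinAlgError):
            score = float("inf")  # infeasible trial (e.g. log of <= 0)
        if not score >= 0:  # NaN guard
            score = float("inf")
        history.append(TrialRecord(index=i, params=params, cv_mse=score,
                                   seed=seed))
    best = min(history, key=lambda t: t.cv_mse)
    return dict(best.params), history


def trials_to_frame(history: list[TrialRecord]) -> pd.DataFrame:
    """Trial history as a flat table."""
    return pd.DataFrame([{"trial": t.index, **t.params, "cv_mse": t.cv_mse,
                          "seed": t.seed} for t in history])


#: Reference configurations used when no search is run: Matern kernels with a
#: log-transformed target; the viscous coefficient is close to linear in
#: alpha (degree 1) while the expansion coefficient benefits from quadratic
#: mode interactions (degree 2).
DEFAULT_CONFIGS = {
    "kv": ({"family": "Matern", "nu": 1.5, "c_scale": 55.0,
            "noise_var": 6.1e-2, "degree": 1, "log_target": True}),
    "kt": ({"family": "Matern", "nu": 0.5, "c_scale": 9.3e4,
            "noise_var": 1.4e-4, "degree": 2, "log_target": True}),
}


def train_target(table: pd.DataFrame, target: str, n_trials: int = 20,
                 k: int = 5, seed: int = 0, sampler: str = "tpe"
                 ) -> tuple[GPRModel, pd.DataFrame]:
    """Train one loss-coefficient regressor from a training table.

    ``table`` holds `alpha_*` columns plus the target column (`kv` or
    `kt`).  With ``n_trials == 0`` the reference configuration for the
    target is used directly instead of searching.
    """
    alpha_cols = [c for c in table.columns if c.startswith("alpha_")]
    X = table[alpha_cols].to_numpy(float)
    y = table[target].to_numpy(float)
    if n_trials > 0:
        params, history = hyperparameter_search(X, y, n_trials=n_trials,
                                                k=k, seed=seed,
                                                sampler=sampler)
        trials = trials_to_frame(history)
    else:
        params = dict(DEFAULT_CONFIGS[target])
        trials = pd.DataFrame()
    cfg, tr = _params_to_config({"nu": None, **params})
    model = gpr_fit(X, y, cfg, tr, seed=seed, target_name=target)
    return model, trials
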