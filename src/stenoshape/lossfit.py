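"""Two-regime least-squares estimation of the loss coefficients Kv and Kt.

The lumped stenosis element writes the trans-stenotic drop as

    dp = Kv * h1(q) + Kt * h2(q^2),
    h1(q) = 8 mu ls q / (pi a0^4),      h2(q^2) = rho/2 * (q / (pi a0^2))^2.

Per geometry, the (q, dp) samples are split at Re = 10.  In the low-Reynolds
regime (Re < 10) the quadratic term is neglected and Kv comes from an
ordinary least-squares fit of dp against h1 through the origin; in the
high-Reynolds regime (Re >= 10) the previously determined linear term is
subtracted and Kt comes from an origin fit of the residual against h2.
Excluded (> 60 mmHg) and non-converged samples are dropped before fitting
by default.  Negative fitted coefficients are reported with a warning, not
clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import FitError, FluidConstants

#: Reynolds number splitting the two fitting regimes; Re = 10 itself belongs
#: to the high-Reynolds subset.
REGIME_SPLIT_RE = 10.0


def h_terms(q: float, consts: FluidConstants) -> tuple[float, float]:
    """The linear and quadratic flow terms (both in Pa) for flow ``q``."""
    q = np.asarray(q, dtype=float)
    h1q = 8.0 * consts.mu * consts.ls * q / (np.pi * consts.a0 ** 4)
    h2q2 = 0.5 * consts.rho * (q / (np.pi * consts.a0 ** 2)) ** 2
    if q.ndim == 0:
        return float(h1q), float(h2q2)
    return h1q, h2q2


@dataclass(frozen=True)
class LossCoefficients:
    """Fitted per-geometry loss coefficients and the sample counts used."""

    geometry_id: str
    kv: float
    kt: float
    n_low: int
    n_high: int


def fit_loss_coefficients(samples: pd.DataFrame, consts: FluidConstants,
                          drop_flagged: bool = True) -> LossCoefficients:
    """Fit (Kv, Kt) for one geometry from its campaign rows.

    ``samples`` uses the campaign schema (`re`, `q_m3s`, `dp_sten_pa`,
    `converged`, `excluded`); all rows must belong to a single geometry.
    """
    gids = samples["geometry_id"].unique() if "geometry_id" in samples else [""]
    if len(gids) > 1:
        raise ValueError("fit_loss_coefficients expects a single geometry")
    gid = str(gids[0])
    usable = samples
    if drop_flagged:
        usable = samples[samples["converged"] & ~samples["excluded"]]
    low = usable[usable["re"] < REGIME_SPLIT_RE]
    high = usable[usable["re"] >= REGIME_SPLIT_RE]
    if len(low) == 0:
        raise FitError(f"{gid}: no usable low-Reynolds samples")
    if len(high) == 0:
        raise FitError(f"{gid}: no usable high-Reynolds samples")

    h1_low, _ = h_terms(low["q_m3s"].to_numpy(), consts)
    dp_low = low["dp_sten_pa"].to_numpy()
    kv = float(np.dot(dp_low, h1_low) / np.dot(h1_low, h1_low))

    h1_high, h2_high = h_terms(high["q_m3s"].to_numpy(), consts)
    resid = high["dp_sten_pa"].to_numpy() - kv * h1_high
    kt = float(np.dot(resid, h2_high) / np.dot(h2_high, h2_high))

    if kv < 0 or kt < 0:
        warnings.warn(f"{gid}: negative fitted loss coefficient "
                      f"(kv={kv:.3g}, kt={kt:.3g})", stacklevel=2)
    return LossCoefficients(geometry_id=gid, kv=kv, kt=kt,
                            n_low=len(low), n_high=len(high))


def fit_campaign(campaign: pd.DataFrame, consts: FluidConstants,
                 drop_flagged: bool = True) -> pd.DataFrame:
    """Fit loss coefficients for every geometry in a campaign table."""
    rows = []
    for gid, group in campaign.groupby("geometry_id", sort=True):
        c = fit_loss_coefficients(group, consts, drop_flagged=drop_flagged)
        rows.append((c.geometry_id, c.kv, c.kt, c.n_low, c.n_high))
    return pd.DataFrame(rows, columns=["geometry_id", "kv", "kt",
                                       "n_low", "n_high"])


def build_training_table(loss: pd.DataFrame,
                         alphas: pd.DataFrame) -> pd.DataFrame:
    """Join fitted loss coefficients with the shape-coefficient table."""
    merged = alphas.merge(loss, left_on="id", right_on="geometry_id",
                          how="inner")
    return merged.drop(columns=["geometry_id"])
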