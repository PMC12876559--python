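"""The deliverable 0D stenosis element and the Heinen comparator.

Given a geometry's shape coefficients alpha, the element predicts the
trans-stenotic pressure drop at flow q as

    dp = Kv_hat(alpha) * h1(q) + Kt_hat(alpha) * h2(q^2),

with the loss coefficients supplied by the trained GP regressors.  For
network coupling the same relation is exposed as a flow-dependent
resistance R(Q) = Kv 8 mu ls/(pi a0^4) + Kt rho/(2 pi^2 a0^4) |Q|_sm with
under-relaxation of the coupling flow magnitude (smoothing factor 0.3) to
stay stable through near-zero and reversed systolic flow.  FFR is the
pressure-drop surrogate 1 - dp / P_aorta with P_aorta = 100 mmHg.

The geometry-based comparator of Heinen and colleagues writes the quadratic
term through the Borda-Carnot area-ratio factor of the minimal lumen:

    dp = Kv 8 mu ls/(pi a0^4) q + Kt rho/(2 pi^2 a0^4) ((a0/a_s)^2 - 1)^2 q^2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import FluidConstants
from .lossfit import h_terms
from .regression import GPRModel, gpr_predict
from .shape import ShapeCoefficients, ShapeModel


@dataclass(frozen=True)
class StenosisModelBundle:
    """Shape model plus the two trained loss-coefficient regressors."""

    shape_model: ShapeModel | None
    kv_model: GPRModel
    kt_model: GPRModel
    consts: FluidConstants

    def coefficient_posteriors(self, alpha: np.ndarray
                               ) -> tuple[float, float, float, float]:
        """(Kv mean, Kv sd, Kt mean, Kt sd) for one alpha vector."""
        a = np.atleast_2d(np.asarray(
            alpha.alpha if isinstance(alpha, ShapeCoefficients) else alpha,
            dtype=float))
        kv, kv_sd = gpr_predict(self.kv_model, a)
        kt, kt_sd = gpr_predict(self.kt_model, a)
        return float(kv[0]), float(kv_sd[0]), float(kt[0]), float(kt_sd[0])


def predict_dp(bundle: StenosisModelBundle,
               alpha: ShapeCoefficients | np.ndarray,
               q: float) -> tuple[float, float]:
    """Predicted pressure drop (Pa) and its propagated uncertainty.

    The two coefficient posteriors are treated as independent, so
    sd = sqrt((h1 sd_Kv)^2 + (h2 sd_Kt)^2).
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    kv, kv_sd, kt, kt_sd = bundle.coefficient_posteriors(alpha)
    h1q, h2q2 = h_terms(q, bundle.consts)
    dp = kv * h1q + kt * h2q2
    dp_sigma = float(np.hypot(h1q * kv_sd, h2q2 * kt_sd))
    return float(dp), dp_sigma


@dataclass(frozen=True)
class HeinenGeometry:
    """Inputs of the geometry-based comparator model."""

    a0: float
    a_s: float
    ls: float
    kv: float
    kt: float

    def __post_init__(self) -> None:
        if not (0 < self.a_s <= self.a0):
            raise ValueError("a_s must satisfy 0 < a_s <= a0")
        if self.ls <= 0:
            raise ValueError("ls must be positive")


def heinen_dp(geom: HeinenGeometry, q: float,
              consts: FluidConstants) -> float:
    """Pressure drop of the cosinusoidal-lesion comparator model."""
    if q < 0:
        raise ValueError("q must be non-negative")
    lin = geom.kv * 8.0 * consts.mu * geom.ls * q / (np.pi * geom.a0 ** 4)
    ratio = (geom.a0 / geom.a_s) ** 2 - 1.0
    quad = (geom.kt * consts.rho / (2.0 * np.pi ** 2 * geom.a0 ** 4)
            * ratio ** 2 * q ** 2)
    return float(lin + quad)


@dataclass(frozen=True)
class WaveformState:
    """Under-relaxed coupling-flow state of the 0D element."""

    alpha_relax: float = 0.3
    q_smoothed: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_relax < 1):
            raise ValueError("alpha_relax must lie in [0, 1)")
        if self.q_smoothed < 0:
            raise ValueError("q_smoothed must be non-negative")


def smooth_flow(state: WaveformState, q_raw: float) -> WaveformState:
    """One under-relaxation step on the coupling flow magnitude."""
    q_new = (state.alpha_relax * state.q_smoothed
             + (1.0 - state.alpha_relax) * abs(q_raw))
    return replace(state, q_smoothed=q_new)


def resistance(kv: float, kt: float, q_smoothed: float,
               consts: FluidConstants) -> float:
    """Flow-dependent resistance of the lumped element (Pa*s/m^3)."""
    if q_smoothed < 0:
        raise ValueError("q_smoothed must be non-negative")
    return (kv * 8.0 * consts.mu * consts.ls / (np.pi * consts.a0 ** 4)
            + kt * consts.rho / (2.0 * np.pi ** 2 * consts.a0 ** 4)
            * q_smoothed)


def ffr_from_dp(dp: float, p_aorta: float) -> float:
    """FFR surrogate 1 - dp / P_aorta (reported unclipped)."""
    if p_aorta <= 0:
        raise ValueError("p_aorta must be positive")
    return 1.0 - dp / p_aorta


def run_waveform(bundle: StenosisModelBundle,
                 alpha: ShapeCoefficients | np.ndarray,
                 q_series: np.ndarray,
                 p_aorta: float | np.ndarray | None = None,
                 alpha_relax: float = 0.3
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Drive the 0D element with a signed flow waveform.

    Per step the coupling magnitude is under-relaxed, the resistance is
    updated, and the signed drop is dP = R * Q (so reversed flow yields a
    reversed drop).  Returns the smoothed-flow series, the dp series and
    the time-averaged FFR (mean of (P_aorta - dp)/P_aorta over the series).
    """
    q_series = np.asarray(q_series, dtype=float)
    if q_series.size == 0:
        raise ValueError("q_series must be non-empty")
    if p_aorta is None:
        p_aorta = bundle.consts.p_aorta
    p_series = np.broadcast_to(np.asarray(p_aorta, dtype=float),
                               q_series.shape)
    kv, _, kt, _ = bundle.coefficient_posteriors(alpha)
    # initialize at |q(0)| to avoid an artificial startup transient
    state = WaveformState(alpha_relax=alpha_relax,
                          q_smoothed=abs(float(q_series[0])))
    q_sm = np.empty_like(q_series)
    dp = np.empty_like(q_series)
    for i, q in enumerate(q_series):
        state = smooth_flow(state, float(q))
        q_sm[i] = state.q_smoothed
        dp[i] = resistance(kv, kt, state.q_smoothed, bundle.consts) * q
    ffr = float(np.mean((p_series - dp) / p_series))
    return q_sm, dp, ffr


def coronary_waveform(n_steps: int = 400, period: float = 0.8,
                      q_mean: float = 3.33e-6, systolic_fraction: float = 0.35,
                      reverse_peak: float = 0.15
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Parameterized two-phase coronary-like flow waveform (synthetic).

    Diastole carries most of the flow; systole shows suppressed and briefly
    reversed flow, the regime the under-relaxation step is designed to
    survive.  Returns (t, q) over one period with mean flow ``q_mean``.
    """
    t = np.linspace(0.0, period, n_steps, endpoint=False)
    phase = t / period
    q = np.where(
        phase < systolic_fraction,
        # systolic dip with a short reversed-flow notch
        -reverse_peak * np.sin(np.pi * phase / systolic_fraction),
        np.sin(np.pi * (phase - systolic_fraction)
               / (1.0 - systolic_fraction)) ** 2,
    )
    q = q / q.mean() * q_mean
    return t, q
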