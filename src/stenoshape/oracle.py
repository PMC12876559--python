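"""Reference pressure-drop generator (desk-scale stand-in for 3-D CFD).

For each geometry and Reynolds number the oracle produces the trans-stenotic
pressure drop from a deterministic, geometry-dependent ground truth that
lies exactly in the two-term lumped model family:

    dp_sten = kv_star * h1(q) + kt_star * h2(q^2)

with the viscous coefficient obtained by integrating the Poiseuille
resistance of the splined lumen over the lesion window,

    kv_star = (1/ls) * Int_lesion (a0 / a(z))^4 dz,

and the expansion coefficient given by the Borda-Carnot sudden-expansion
loss at the minimal lumen,

    kt_star = ((a0 / a_min)^2 - 1)^2.

Because the ground truth lies in the model family, the downstream fitting
and regression stages can be validated by exact parameter recovery.
Optional multiplicative log-normal noise, a Reynolds-dependent model
mismatch term, and random convergence failures emulate the imperfections of
a real CFD campaign.  Samples whose stenotic drop exceeds the physiological
cap (60 mmHg) are flagged as excluded but retained in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import FluidConstants, GenerationError, mmhg_to_pa
from .geometry import RadiusProfile, append_cfd_extension
from .lossfit import h_terms

#: Lesion integration window for kv_star: the planes 6-15 span widened by
#: half a plane spacing on each side, so the window length equals ls = 10 mm
#: and a straight tube integrates to exactly 1.
LESION_WINDOW = (4.5e-3, 14.5e-3)
#: Quadrature resolution, subdivisions per millimetre of lesion.
_QUAD_PER_MM = 40


@dataclass(frozen=True)
class OracleConfig:
    """Noise and failure knobs of the reference-data generator."""

    noise_sd: float = 0.0
    mismatch_gain: float = 0.0
    fail_prob: float = 0.0
    seed: int = 0
    dp_cap: float = mmhg_to_pa(60.0)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.fail_prob < 1):
            raise ValueError("fail_prob must lie in [0, 1)")
        if self.dp_cap <= 0:
            raise ValueError("dp_cap must be positive")


@dataclass(frozen=True)
class FlowSample:
    """One (geometry, Reynolds) evaluation of the reference generator."""

    geometry_id: str
    re: float
    q: float
    dp_total: float
    dp_pois: float
    dp_sten: float
    converged: bool = True
    excluded: bool = False


def reynolds_to_flow(re: float, consts: FluidConstants) -> float:
    """Volumetric flow (m^3/s) giving Reynolds number ``re`` at the inlet.

    Inverts Re = rho * v_avg * D / mu with v_avg = q / (pi a0^2), D = 2 a0.
    """
    if re < 0:
        raise ValueError("Reynolds number must be non-negative")
    return re * consts.mu * np.pi * consts.a0 / (2.0 * consts.rho)


def flow_to_reynolds(q: float, consts: FluidConstants) -> float:
    """Reynolds number at the inlet for volumetric flow ``q`` (m^3/s)."""
    return 2.0 * consts.rho * q / (consts.mu * np.pi * consts.a0)


def poiseuille_drop(q: float, length: float, consts: FluidConstants) -> float:
    """Fully developed laminar drop 8 mu L q / (pi a0^4) over a straight tube."""
    if q < 0 or length < 0:
        raise ValueError("q and length must be non-negative")
    return 8.0 * consts.mu * length * q / (np.pi * consts.a0 ** 4)


def cfl_time_step(dx_min: float, u_char: float) -> float:
    """Explicit-CFL time step dx_min / u_char (documents the replaced CFD
    solver setup; not used by the oracle itself)."""
    if dx_min <= 0 or u_char <= 0:
        raise ValueError("dx_min and u_char must be positive")
    return dx_min / u_char


def oracle_coefficients(profile: RadiusProfile,
                        consts: FluidConstants) -> tuple[float, float]:
    """Ground-truth (kv_star, kt_star) for one geometry.

    kv_star integrates (a0/a(z))^4 over the lesion window on the splined
    radius (trapezoidal quadrature, >= 20 subdivisions per mm) and
    normalises by ls; kt_star is the Borda-Carnot coefficient at the
    minimal splined radius.
    """
    spline = profile.spline()
    z0 = max(LESION_WINDOW[0], float(profile.plane_z[0]))
    z1 = min(LESION_WINDOW[1], float(profile.plane_z[-1]))
    n = int(round((z1 - z0) * 1e3 * _QUAD_PER_MM)) + 1
    z = np.linspace(z0, z1, n)
    a = spline(z)
    if np.any(a <= 0):
        raise GenerationError("non-positive radius in the lesion window")
    kv_star = float(np.trapezoid((consts.a0 / a) ** 4, z) / consts.ls)
    a_min = min(float(a.min()), float(profile.radii.min()))
    kt_star = float(((consts.a0 / a_min) ** 2 - 1.0) ** 2)
    return kv_star, kt_star


def simulate_pressure_drop(profile: RadiusProfile, re: float,
                           cfg: OracleConfig, consts: FluidConstants,
                           geometry_id: str = "",
                           rng: np.random.Generator | None = None,
                           coefficients: tuple[float, float] | None = None
                           ) -> FlowSample:
    """One reference sample for an (extended) geometry at one Reynolds number."""
    if not profile.has_extension:
        raise ValueError("simulate_pressure_drop requires an extended profile")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    q = reynolds_to_flow(re, consts)
    kv_star, kt_star = (coefficients if coefficients is not None
                        else oracle_coefficients(profile, consts))
    h1q, h2q2 = h_terms(q, consts)
    dp_sten = kv_star * h1q + kt_star * h2q2
    if cfg.noise_sd > 0:
        dp_sten *= np.exp(rng.normal(0.0, cfg.noise_sd))
    if cfg.mismatch_gain != 0:
        dp_sten += cfg.mismatch_gain * (re / 500.0) * kv_star * h1q
    converged = True
    if cfg.fail_prob > 0 and rng.random() < cfg.fail_prob:
        converged = False
    dp_pois = poiseuille_drop(q, consts.lext, consts)
    return FlowSample(geometry_id=geometry_id, re=float(re), q=float(q),
                      dp_total=float(dp_sten + dp_pois),
                      dp_pois=float(dp_pois), dp_sten=float(dp_sten),
                      converged=converged,
                      excluded=bool(dp_sten > cfg.dp_cap))


CAMPAIGN_COLUMNS = ("geometry_id", "re", "q_m3s", "dp_total_pa", "dp_pois_pa",
                    "dp_sten_pa", "converged", "excluded", "source")


def run_campaign(profiles: list[RadiusProfile], cfg: OracleConfig,
                 consts: FluidConstants,
                 geometry_ids: list[str] | None = None) -> pd.DataFrame:
    """Full-factorial campaign: one sample per (geometry, Reynolds number).

    Unextended profiles are extended on the fly.  Excluded and
    non-converged rows are flagged, never dropped.
    """
    if len(profiles) == 0:
        raise ValueError("the cohort must be non-empty")
    if geometry_ids is None:
        geometry_ids = [f"geom_{k:04d}" for k in range(len(profiles))]
    rows = []
    for k, (gid, profile) in enumerate(zip(geometry_ids, profiles)):
        if not profile.has_extension:
            profile = append_cfd_extension(profile, consts)
        coeffs = oracle_coefficients(profile, consts)
        for j, re in enumerate(consts.re_list):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, k, j]))
            s = simulate_pressure_drop(profile, re, cfg, consts,
                                       geometry_id=gid, rng=rng,
                                       coefficients=coeffs)
            rows.append((s.geometry_id, s.re, s.q, s.dp_total, s.dp_pois,
                         s.dp_sten, s.converged, s.excluded, "oracle"))
    return pd.DataFrame(rows, columns=list(CAMPAIGN_COLUMNS))
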