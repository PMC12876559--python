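"""Synthetic axisymmetric stenotic lesion geometries.

A vessel is described on 20 equidistant cross-sectional planes (1 mm apart,
plane ``i`` at z = (i-1) mm, 1-based indices throughout to match the
Plane 1..21 convention).  Planes 1-5 and 16-20 stay at the healthy reference
radius ``a0``; a single focal lesion is carved into the central segment
(planes 6-15) as a Gaussian radius reduction

    a_i = a0 - (a0 - a_s) * exp(-(i - c_sten)^2 / (2 sigma^2)) * (1 + eps_i)

where ``a_s = (1 - S_sev) * a0`` is the minimal lesion radius, ``c_sten`` the
minimum-severity plane, ``sigma`` the taper width (plane units) and ``eps_i``
a +/-10% per-plane perturbation that is never applied at ``c_sten`` itself.
Severities are drawn from a low-discrepancy Sobol sequence so the cohort is
uniformly stratified over the clinically ambiguous 30%-80% window.

For the reference flow campaign a cylindrical outflow extension of ten
reference diameters (30 mm) is appended as plane 21, giving a 35 mm total
outlet extension.  Profiles are lofted into axisymmetric surface meshes on a
fixed (nz x ntheta) vertex grid shared by the whole cohort, which gives
point correspondence for shape modeling by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.stats import qmc

from .constants import FluidConstants, GenerationError, StateError

#: Axial spacing between cross-sectional planes, m.
PLANE_SPACING = 1.0e-3
#: Number of planes of the unextended vessel.
N_PLANES = 20
#: First and last plane of the central lesion segment (1-based, inclusive).
LESION_FIRST_PLANE = 6
LESION_LAST_PLANE = 15
#: Extension length in reference diameters.
EXTENSION_DIAMETERS = 10.0

#: Default circumferential and axial sampling of the lofted surface.
DEFAULT_NTHETA = 32
#: Axial surface samples per millimetre of vessel.
DEFAULT_NZ_PER_MM = 4


def truncate_toward_zero(x: float) -> int:
    """Truncate ``x`` toward zero: floor for x >= 0, ceil for x < 0."""
    if not math.isfinite(x):
        raise ValueError("truncate_toward_zero requires a finite argument")
    return math.floor(x) if x >= 0 else math.ceil(x)


def center_plane(s_sten: int, e_sten: int, beta: float) -> int:
    """Minimum-severity plane from the boundary planes and the draw ``beta``.

    ``c_sten = s_sten + 2 + T(beta * (e_sten - s_sten - 3))`` with T the
    truncation toward zero.  When the initial region spans only two planes
    (s_sten=10, e_sten=11) the result can fall on plane 12, outside the
    initial region; that edge case is accepted and simply widens the lesion.
    """
    return s_sten + 2 + truncate_toward_zero(beta * (e_sten - s_sten - 3))


def sample_severities(n: int, lo: float = 0.3, hi: float = 0.8,
                      seed: int = 0) -> np.ndarray:
    """Draw ``n`` stenosis severities from a Sobol sequence scaled to [lo, hi].

    The unscrambled radical-inverse sequence is used: for n a power of two
    the points are exactly {k/n}, so any equal-width binning of the cohort
    is as uniform as arithmetically possible.  The ``seed`` argument is
    accepted for interface stability; the severity stream is deliberately
    deterministic so the severity distribution is invariant to the nuisance
    draws (boundary planes, taper width, noise).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 < lo < hi < 1):
        raise ValueError("severity bounds must satisfy 0 < lo < hi < 1")
    with warnings.catch_warnings():
        # scipy warns when n is not a power of two; balance is still fine
        # for the cohort sizes used here.
        warnings.simplefilter("ignore", UserWarning)
        u = qmc.Sobol(d=1, scramble=False, seed=seed).random(n).ravel()
    return lo + (hi - lo) * u


def sample_lesion_planes(rng: np.random.Generator
                         ) -> tuple[int, int, float, int, float]:
    """Draw (s_sten, e_sten, beta, c_sten, sigma) for one lesion."""
    s_sten = int(rng.integers(6, 11))
    e_sten = int(rng.integers(11, 16))
    beta = float(rng.random())
    sigma = float(rng.uniform(1.0, 3.0))
    return s_sten, e_sten, beta, center_plane(s_sten, e_sten, beta), sigma


@dataclass(frozen=True)
class GenerationParams:
    """Sampled parameters fully determining one synthetic lesion."""

    s_sev: float
    s_sten: int
    e_sten: int
    beta: float
    c_sten: int
    sigma: float
    eps: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.3 <= self.s_sev <= 0.8):
            raise ValueError("s_sev must lie in [0.3, 0.8]")
        if self.s_sten not in range(6, 11) or self.e_sten not in range(11, 16):
            raise ValueError("boundary planes out of range")
        if self.c_sten != center_plane(self.s_sten, self.e_sten, self.beta):
            raise ValueError("c_sten inconsistent with (s_sten, e_sten, beta)")
        if not (1.0 <= self.sigma <= 3.0):
            raise ValueError("sigma must lie in [1, 3]")
        eps = tuple(float(e) for e in self.eps)
        if len(eps) != N_PLANES:
            raise ValueError(f"eps must have {N_PLANES} entries")
        if any(abs(e) > 0.1 for e in eps):
            raise ValueError("eps entries must lie in [-0.1, 0.1]")
        if eps[self.c_sten - 1] != 0.0:
            raise ValueError("eps at c_sten must be exactly 0")
        object.__setattr__(self, "eps", eps)

    @property
    def lesion_planes(self) -> range:
        """1-based planes carrying a radius reduction (includes the plane-12
        edge case where c_sten falls just outside [s_sten, e_sten])."""
        return range(min(self.s_sten, self.c_sten),
                     max(self.e_sten, self.c_sten) + 1)


def sample_generation_params(s_sev: float, rng: np.random.Generator,
                             seed: int = 0) -> GenerationParams:
    """Draw the nuisance parameters (planes, taper, noise) for one severity."""
    s_sten, e_sten, beta, c_sten, sigma = sample_lesion_planes(rng)
    eps = np.zeros(N_PLANES)
    lo, hi = min(s_sten, c_sten), max(e_sten, c_sten)
    eps[lo - 1:hi] = rng.uniform(-0.1, 0.1, size=hi - lo + 1)
    eps[c_sten - 1] = 0.0
    return GenerationParams(s_sev=float(s_sev), s_sten=s_sten, e_sten=e_sten,
                            beta=beta, c_sten=c_sten, sigma=sigma,
                            eps=tuple(eps), seed=seed)


@dataclass(frozen=True)
class RadiusProfile:
    """Axisymmetric vessel: per-plane axial position and radius (SI units)."""

    plane_z: np.ndarray
    radii: np.ndarray
    a_s: float
    has_extension: bool = False
    params: GenerationParams | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.plane_z, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if z.shape != r.shape or z.ndim != 1:
            raise ValueError("plane_z and radii must be matching 1-D arrays")
        if np.any(r <= 0):
            raise GenerationError("all radii must be strictly positive")
        object.__setattr__(self, "plane_z", z)
        object.__setattr__(self, "radii", r)

    @property
    def n_planes(self) -> int:
        return self.plane_z.size

    def spline(self) -> CubicSpline:
        """Natural cubic spline of radius versus axial position."""
        return CubicSpline(self.plane_z, self.radii, bc_type="natural")


def build_radius_profile(params: GenerationParams,
                         consts: FluidConstants) -> RadiusProfile:
    """Evaluate the Gaussian taper on the 20 planes for one lesion."""
    a0 = consts.a0
    a_s = (1.0 - params.s_sev) * a0
    z = np.arange(N_PLANES) * PLANE_SPACING
    radii = np.full(N_PLANES, a0)
    for i in params.lesion_planes:
        g = math.exp(-((i - params.c_sten) ** 2) / (2.0 * params.sigma ** 2))
        radii[i - 1] = a0 - (a0 - a_s) * g * (1.0 + params.eps[i - 1])
    radii[params.c_sten - 1] = a_s  # target reduction exact, never noised
    if np.any(radii <= 0):
        raise GenerationError("noise produced a non-positive radius; "
                              "redraw eps and retry")
    return RadiusProfile(plane_z=z, radii=radii, a_s=a_s, params=params)


def append_cfd_extension(profile: RadiusProfile,
                         consts: FluidConstants) -> RadiusProfile:
    """Append the cylindrical outflow extension (10 reference diameters)."""
    if profile.has_extension:
        raise StateError("profile already carries a CFD extension")
    if profile.n_planes != N_PLANES:
        raise ValueError(f"expected a {N_PLANES}-plane profile")
    ext = EXTENSION_DIAMETERS * 2.0 * consts.a0
    z = np.append(profile.plane_z, profile.plane_z[-1] + ext)
    r = np.append(profile.radii, consts.a0)
    return replace(profile, plane_z=z, radii=r, has_extension=True)


@dataclass(frozen=True)
class TubeMesh:
    """Lofted axisymmetric surface on a fixed (nz x ntheta) vertex grid.

    Vertices are stored row-major by axial ring: vertex (iz, itheta) is
    ``vertices[iz * ntheta + itheta]``.  Every cohort member shares the same
    grid topology, so template-to-target correspondence is positional.
    """

    nz: int
    ntheta: int
    vertices: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.shape != (self.nz * self.ntheta, 3):
            raise ValueError("vertex count must equal nz * ntheta")
        object.__setattr__(self, "vertices", v)

    def grid(self) -> np.ndarray:
        """Vertices reshaped to (nz, ntheta, 3)."""
        return self.vertices.reshape(self.nz, self.ntheta, 3)

    def ring_z(self) -> np.ndarray:
        """Axial position of each ring."""
        return self.grid()[:, 0, 2]

    def ring_radii(self) -> np.ndarray:
        """Radius of each axial ring (axisymmetric by construction)."""
        g = self.grid()
        return np.hypot(g[:, :, 0], g[:, :, 1]).mean(axis=1)

    def to_trimesh(self):
        """Triangulated open-tube surface (for STL/PLY export)."""
        import trimesh

        faces = []
        nt = self.ntheta
        for iz in range(self.nz - 1):
            for it in range(nt):
                a = iz * nt + it
                b = iz * nt + (it + 1) % nt
                c = (iz + 1) * nt + it
                d = (iz + 1) * nt + (it + 1) % nt
                faces.append((a, b, d))
                faces.append((a, d, c))
        return trimesh.Trimesh(vertices=self.vertices,
                               faces=np.asarray(faces), process=False)


def default_nz(profile_span_m: float) -> int:
    """Default axial sample count: 4 samples per mm plus the end point."""
    return int(round(profile_span_m / PLANE_SPACING)) * DEFAULT_NZ_PER_MM + 1


def loft_surface(profile: RadiusProfile, nz: int | None = None,
                 ntheta: int = DEFAULT_NTHETA,
                 source_id: str = "") -> TubeMesh:
    """Loft a radius profile into an axisymmetric surface mesh.

    The radius between planes is interpolated with a natural cubic spline
    (interpolation is exact at the plane stations).
    """
    if nz is None:
        nz = default_nz(profile.plane_z[-1] - profile.plane_z[0])
    if nz < profile.n_planes:
        raise ValueError("nz must be at least the number of planes")
    if ntheta < 8:
        raise ValueError("ntheta must be at least 8")
    z = np.linspace(profile.plane_z[0], profile.plane_z[-1], nz)
    r = profile.spline()(z)
    if np.any(r <= 0):
        raise GenerationError("spline interpolation produced a non-positive "
                              "radius")
    theta = 2.0 * np.pi * np.arange(ntheta) / ntheta
    x = np.outer(r, np.cos(theta))
    y = np.outer(r, np.sin(theta))
    zz = np.repeat(z[:, None], ntheta, axis=1)
    vertices = np.stack([x, y, zz], axis=-1).reshape(-1, 3)
    return TubeMesh(nz=nz, ntheta=ntheta, vertices=vertices,
                    source_id=source_id)


MANIFEST_COLUMNS = ("id", "s_sev", "s_sten", "e_sten", "c_sten", "sigma",
                    "seed", "profile_path", "mesh_path")

#: Maximum redraws of the per-plane noise before giving up on a geometry.
_MAX_EPS_REDRAWS = 100


def generate_cohort(n: int, seed: int, consts: FluidConstants | None = None,
                    lo: float = 0.3, hi: float = 0.8,
                    ntheta: int = DEFAULT_NTHETA,
                    ) -> tuple[list[RadiusProfile], list[TubeMesh],
                               pd.DataFrame]:
    """Generate a seeded cohort of ``n`` lesion geometries.

    Returns the (unextended) radius profiles, the lofted surface meshes, and
    a manifest table.  Severities come from the Sobol stream; all nuisance
    draws come from an independent seeded substream, so the severity
    distribution never depends on the nuisance settings.  Bitwise
    reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    consts = consts or FluidConstants()
    severities = sample_severities(n, lo=lo, hi=hi, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    profiles: list[RadiusProfile] = []
    meshes: list[TubeMesh] = []
    rows = []
    for k, s_sev in enumerate(severities):
        gid = f"geom_{k:04d}"
        for _ in range(_MAX_EPS_REDRAWS):
            params = sample_generation_params(s_sev, rng, seed=seed)
            try:
                profile = build_radius_profile(params, consts)
                break
            except GenerationError:
                continue
        else:  # pragma: no cover - unreachable with the stated noise bounds
            raise GenerationError(f"could not generate geometry {gid}")
        mesh = loft_surface(profile, ntheta=ntheta, source_id=gid)
        profiles.append(profile)
        meshes.append(mesh)
        rows.append({"id": gid, "s_sev": float(s_sev),
                     "s_sten": params.s_sten, "e_sten": params.e_sten,
                     "c_sten": params.c_sten, "sigma": params.sigma,
                     "seed": seed,
                     "profile_path": f"{gid}_profile.csv",
                     "mesh_path": f"{gid}.stl"})
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    return profiles, meshes, manifest


# ---------------------------------------------------------------------------
# File I/O


def profile_to_frame(profile: RadiusProfile) -> pd.DataFrame:
    """Profile as a `plane,z_mm,radius_mm` table (1-based plane index)."""
    return pd.DataFrame({
        "plane": np.arange(1, profile.n_planes + 1),
        "z_mm": profile.plane_z / PLANE_SPACING,
        "radius_mm": profile.radii / PLANE_SPACING,
    })


def profile_from_frame(frame: pd.DataFrame,
                       consts: FluidConstants | None = None) -> RadiusProfile:
    """Rebuild a profile from a `plane,z_mm,radius_mm` table."""
    consts = consts or FluidConstants()
    z = frame["z_mm"].to_numpy(float) * PLANE_SPACING
    r = frame["radius_mm"].to_numpy(float) * PLANE_SPACING
    return RadiusProfile(plane_z=z, radii=r, a_s=float(r.min()),
                         has_extension=z.size > N_PLANES)


def save_cohort(out_dir, profiles, meshes, manifest) -> None:
    """Write manifest CSV, per-geometry profile CSVs and STL meshes."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    for row, profile, mesh in zip(manifest.itertuples(), profiles, meshes):
        profile_to_frame(profile).to_csv(out / row.profile_path, index=False)
        mesh.to_trimesh().export(out / row.mesh_path)
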