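"""Statistical shape model of the lesion cohort.

Every cohort mesh lives on the same (nz x ntheta) vertex grid as the
straight-tube template, so template-to-target correspondence is exact by
construction and each geometry is represented by its per-vertex displacement
field from the template (flattened x-block / y-block / z-block, length 3*Nv).
Principal component analysis of the displacement matrix yields a mean
deformation plus orthonormal shape modes; a geometry is then encoded by the
low-dimensional coefficient vector alpha of its projections onto the leading
modes.

PCA is computed by singular-value decomposition of the centered data matrix
(numerically preferable to forming the 3Nv x 3Nv covariance); sample
variances use the (N - 1) denominator, and each mode's sign is fixed so its
largest-magnitude component is positive, making alpha reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AlignmentError, FluidConstants
from .geometry import (DEFAULT_NTHETA, N_PLANES, PLANE_SPACING, RadiusProfile,
                       TubeMesh, loft_surface)


@dataclass(frozen=True)
class DisplacementVector:
    """Flat template-to-target displacement field (m), x/y/z blocks."""

    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size % 3 != 0:
            raise ValueError("displacement length must be divisible by 3")
        if not np.all(np.isfinite(v)):
            raise ValueError("displacement entries must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ShapeCoefficients:
    """Dimensionless shape-coefficient vector alpha for one geometry."""

    alpha: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha",
                           np.asarray(self.alpha, dtype=float).ravel())


def straight_template(consts: FluidConstants | None = None,
                      nz: int | None = None,
                      ntheta: int = DEFAULT_NTHETA) -> TubeMesh:
    """The fixed straight-tube template (radius a0, planes 1-20)."""
    consts = consts or FluidConstants()
    z = np.arange(N_PLANES) * PLANE_SPACING
    profile = RadiusProfile(plane_z=z, radii=np.full(N_PLANES, consts.a0),
                            a_s=consts.a0)
    return loft_surface(profile, nz=nz, ntheta=ntheta, source_id="template")


def align_to_template(mesh: TubeMesh, template: TubeMesh) -> TubeMesh:
    """Translate a mesh so it is registered to the template frame.

    Two-step pure translation: the mesh is shifted so its minimum z is 0,
    then shifted in x-y so its inlet-ring centroid (mean x, y of the
    vertices at minimum z) matches the template's inlet centroid.  No
    rotation or scaling is applied.
    """
    def inlet_centroid(v: np.ndarray) -> np.ndarray:
        zmin = v[:, 2].min()
        ring = v[np.isclose(v[:, 2], zmin, atol=1e-12)]
        if ring.size == 0:
            raise AlignmentError("empty inlet ring")
        return ring[:, :2].mean(axis=0)

    tv = template.vertices - np.array([0.0, 0.0, template.vertices[:, 2].min()])
    target_c = inlet_centroid(tv)
    v = mesh.vertices.copy()
    v[:, 2] -= v[:, 2].min()
    v[:, :2] += target_c - inlet_centroid(v)
    return TubeMesh(nz=mesh.nz, ntheta=mesh.ntheta, vertices=v,
                    source_id=mesh.source_id)


def displacement_field(template: TubeMesh, target: TubeMesh
                       ) -> DisplacementVector:
    """Per-vertex displacement template -> target, flattened by component."""
    if (template.nz, template.ntheta) != (target.nz, target.ntheta):
        raise ValueError("template and target must share the grid topology")
    d = target.vertices - template.vertices
    return DisplacementVector(
        values=np.concatenate([d[:, 0], d[:, 1], d[:, 2]]),
        source_id=target.source_id)


def vector_to_vertices(values: np.ndarray) -> np.ndarray:
    """Inverse of the x/y/z-block flattening: (3Nv,) -> (Nv, 3)."""
    v = np.asarray(values, dtype=float).ravel()
    nv = v.size // 3
    return np.stack([v[:nv], v[nv:2 * nv], v[2 * nv:]], axis=1)


@dataclass(frozen=True)
class ShapeModel:
    """Mean deformation, orthonormal PCA modes and per-mode variances."""

    template: TubeMesh
    mean: np.ndarray
    modes: np.ndarray          # (n_modes_total, 3Nv), rows orthonormal
    variances: np.ndarray      # non-increasing, (N-1) denominator
    n_su: int
    n_modes_kept: int

    @property
    def n_modes_total(self) -> int:
        return self.modes.shape[0]


def fit_shape_model(displacements: list[DisplacementVector],
                    n_modes: int | str = "auto",
                    var_threshold: float = 0.90,
                    template: TubeMesh | None = None) -> ShapeModel:
    """Fit the PCA shape model to a cohort of displacement fields.

    ``n_modes="auto"`` keeps the smallest number of modes whose cumulative
    variance fraction reaches ``var_threshold``; an integer keeps exactly
    that many.  All modes with nonzero variance are retained in the model so
    full-basis reconstruction is always available.
    """
    if len(displacements) < 2:
        raise ValueError("at least 2 displacement vectors are required")
    X = np.stack([d.values for d in displacements])
    if X.ndim != 2:
        raise ValueError("displacement vectors must have equal length")
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered matrix; keep at most N-1 nontrivial directions.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    n_keep = min(len(displacements) - 1, vt.shape[0])
    s, vt = s[:n_keep], vt[:n_keep]
    variances = s ** 2 / (len(displacements) - 1)
    # Fix the sign of each mode: largest-|component| entry positive.
    for m in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[m]))
        if vt[m, j] < 0:
            vt[m] = -vt[m]
    if template is None:
        raise ValueError("a template mesh must be supplied")
    if n_modes == "auto":
        frac = np.cumsum(variances) / variances.sum()
        kept = int(np.searchsorted(frac, var_threshold) + 1)
    else:
        kept = int(n_modes)
        if kept < 1 or kept > vt.shape[0]:
            raise ValueError("n_modes out of range")
    return ShapeModel(template=template, mean=mean, modes=vt,
                      variances=variances, n_su=len(displacements),
                      n_modes_kept=kept)


def project(model: ShapeModel, disp: DisplacementVector,
            n_modes: int | None = None) -> ShapeCoefficients:
    """Shape coefficients: projections of the centered field on the modes."""
    k = model.n_modes_kept if n_modes is None else int(n_modes)
    if k > model.n_modes_total:
        raise ValueError("n_modes exceeds the available modes")
    if disp.values.size != model.mean.size:
        raise ValueError("displacement length does not match the model")
    alpha = model.modes[:k] @ (disp.values - model.mean)
    return ShapeCoefficients(alpha=alpha, source_id=disp.source_id)


def reconstruct(model: ShapeModel, alpha: ShapeCoefficients | np.ndarray,
                target: TubeMesh | None = None
                ) -> tuple[TubeMesh, float | None]:
    """Rebuild a mesh from shape coefficients.

    Returns the reconstructed mesh and, when a target mesh is supplied, the
    maximum pointwise vertex error in millimetres.
    """
    a = alpha.alpha if isinstance(alpha, ShapeCoefficients) else \
        np.asarray(alpha, dtype=float).ravel()
    if a.size > model.n_modes_total:
        raise ValueError("alpha is longer than the available modes")
    field = model.mean + a @ model.modes[:a.size]
    vertices = model.template.vertices + vector_to_vertices(field)
    mesh = TubeMesh(nz=model.template.nz, ntheta=model.template.ntheta,
                    vertices=vertices, source_id=getattr(alpha, "source_id", ""))
    err = None
    if target is not None:
        err = float(np.linalg.norm(vertices - target.vertices, axis=1).max()
                    / PLANE_SPACING)
    return mesh, err


def explained_variance(model: ShapeModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode and cumulative explained-variance fractions."""
    frac = model.variances / model.variances.sum()
    return frac, np.cumsum(frac)


def project_cohort(model: ShapeModel, meshes: list[TubeMesh],
                   n_modes: int | None = None) -> pd.DataFrame:
    """Alpha table (`id, alpha_1..alpha_k`) for a list of cohort meshes."""
    k = model.n_modes_kept if n_modes is None else int(n_modes)
    rows = []
    for mesh in meshes:
        disp = displacement_field(model.template, mesh)
        coeff = project(model, disp, n_modes=k)
        rows.append([mesh.source_id, *coeff.alpha])
    cols = ["id"] + [f"alpha_{m}" for m in range(1, k + 1)]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Serialization

_SCHEMA_VERSION = 1


def save_model(model: ShapeModel, path) -> None:
    """Portable archive: JSON metadata plus binary arrays (.npz)."""
    meta = {"schema_version": _SCHEMA_VERSION, "n_su": model.n_su,
            "n_modes_kept": model.n_modes_kept,
            "nz": model.template.nz, "ntheta": model.template.ntheta}
    np.savez_compressed(Path(path), meta=json.dumps(meta),
                        template_vertices=model.template.vertices,
                        mean=model.mean, modes=model.modes,
                        variances=model.variances)


def load_model(path) -> ShapeModel:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta["schema_version"] != _SCHEMA_VERSION:
            raise ValueError("unsupported shape-model schema version")
        template = TubeMesh(nz=meta["nz"], ntheta=meta["ntheta"],
                            vertices=z["template_vertices"],
                            source_id="template")
        return ShapeModel(template=template, mean=z["mean"], modes=z["modes"],
                          variances=z["variances"], n_su=meta["n_su"],
                          n_modes_kept=meta["n_modes_kept"])
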