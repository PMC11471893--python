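"""Fiducial-bead registration between imaging spaces (cryo-CLEM).

Correlative light / electron microscopy maps coordinates between modalities
(FM, SEM, TEM) through a similarity transform ``p -> s * R @ p + t`` fitted
by least squares to matched fiducial beads (Umeyama's closed form).  Two
restricted modes mirror the two hardware workflows:

* full similarity (rotation + isotropic scale + translation) for a free-
  standing fluorescence microscope registered to the SEM via bead stacks;
* scale + translation only for an FM integrated into the FIB/SEM, where the
  optical axes are mechanically fixed and only a magnification factor (the
  "scaling factor", ~0.584 between the instruments modelled here) relates
  the images.

Registration accuracy is quantified with the leave-one-out (LOO) metric:
refit the transform without one bead, predict that bead, and report the
per-axis standard deviation of the prediction errors.

Reflections are rejected: if the best-fitting orthogonal matrix has
determinant -1 the fit raises instead of silently flipping handedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BeadSet",
    "SimilarityTransform",
    "RegistrationResult",
    "LOOResult",
    "ReflectionError",
    "DegenerateBeadsError",
    "fit_similarity",
    "apply_transform",
    "estimate_scaling_factor",
    "average_scaling_factor",
    "leave_one_out",
]


class ReflectionError(ValueError):
    """Best-fitting orthogonal matrix is a reflection (det = -1)."""


class DegenerateBeadsError(ValueError):
    """Bead configuration does not determine the requested transform."""


@dataclass
class BeadSet:
    """Labelled fiducial coordinates in one imaging space.

    ``coords`` is (n, d) with d = 2 or 3; ``units`` states the physical unit
    of the coordinates (e.g. "um", "px") and is carried, never converted.
    """

    ids: list
    coords: np.ndarray
    space: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValueError("coords: expected (n, 2) or (n, 3) array, got "
                             f"shape {self.coords.shape}")
        if len(self.ids) != len(self.coords):
            raise ValueError("ids and coords length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ids: duplicate bead labels")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords: non-finite values present")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class SimilarityTransform:
    """``p -> scale * rotation @ p + translation`` in d = 2 or 3 dimensions."""

    rotation: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        d = self.translation.shape[0]
        if self.rotation.shape != (d, d) or d not in (2, 3):
            raise ValueError("rotation/translation dims mismatch or d not in "
                             f"(2, 3): {self.rotation.shape}, ({d},)")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(d),
                           atol=1e-9):
            raise ValueError("rotation: not orthonormal within 1e-9")
        if np.linalg.det(self.rotation) < 0:
            raise ReflectionError("rotation: determinant is -1 (reflection)")
        if not self.scale > 0:
            raise ValueError(f"scale: must be > 0, got {self.scale}")
        self.scale = float(self.scale)

    @property
    def dims(self) -> int:
        return self.translation.shape[0]

    @classmethod
    def identity(cls, dims: int) -> "SimilarityTransform":
        return cls(np.eye(dims), 1.0, np.zeros(dims))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        if points.shape[-1] != self.dims:
            raise ValueError(f"points dimensionality {points.shape[-1]} != "
                             f"transform dims {self.dims}")
        return self.scale * points @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        rot_inv = self.rotation.T
        s_inv = 1.0 / self.scale
        return SimilarityTransform(rot_inv, s_inv,
                                   -s_inv * rot_inv @ self.translation)

    def to_dict(self) -> dict:
        return {
            "dims": self.dims,
            "rotation": self.rotation.tolist(),
            "scale": self.scale,
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(np.asarray(d["rotation"]), d["scale"],
                   np.asarray(d["translation"]))


@dataclass
class RegistrationResult:
    """Fitted transform plus per-bead residuals and the RMSD."""

    transform: SimilarityTransform
    rmsd: float
    n_beads: int
    residuals: np.ndarray = field(repr=False)


@dataclass
class LOOResult:
    """Leave-one-out prediction errors and their per-axis sample SDs."""

    per_bead_errors: np.ndarray  # (n, d): dst - predicted
    sds: np.ndarray              # (d,): sample SD, ddof=1
    n: int
    units: str = ""


def _matched_arrays(src, dst) -> tuple[np.ndarray, np.ndarray, str]:
    """Align two bead sets by id (or accept plain (n, d) arrays)."""
    if isinstance(src, BeadSet) and isinstance(dst, BeadSet):
        if set(src.ids) != set(dst.ids):
            raise ValueError("bead id sets differ between src and dst")
        order = {b: i for i, b in enumerate(dst.ids)}
        idx = [order[b] for b in src.ids]
        return src.coords, dst.coords[idx], dst.units
    a = np.asarray(src, dtype=float)
    b = np.asarray(dst, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("src and dst must be matched (n, d) arrays")
    return a, b, ""


def _check_rank(x_centered: np.ndarray, dims: int) -> None:
    # non-collinear in 2D / non-coplanar in 3D is required to pin rotation
    s = np.linalg.svd(x_centered, compute_uv=False)
    if s[dims - 1] <= 1e-9 * max(s[0], 1e-30):
        kind = "collinear" if dims == 2 else "coplanar"
        raise DegenerateBeadsError(
            f"beads are {kind}: rotation is not determined")


def fit_similarity(src, dst, allow_rotation: bool = True,
                   allow_scale: bool = True) -> RegistrationResult:
    """Least-squares similarity transform from ``src`` onto ``dst``.

    Minimises sum ||dst_i - s R src_i - t||^2 over the enabled degrees of
    freedom.  With ``allow_rotation=False`` (scale + translation only) this
    is the integrated-FM "scaling factor" mode.

    Raises
    ------
    DegenerateBeadsError
        Fewer beads than required (3 in 2D, 4 in 3D for the rotational fit;
        2 for scale-only), or collinear/coplanar configuration.
    ReflectionError
        The unconstrained optimum is a reflection.
    """
    x, y, units = _matched_arrays(src, dst)
    n, d = x.shape

    if allow_rotation:
        n_min = 3 if d == 2 else 4
    else:
        n_min = 2
    if n < n_min:
        raise DegenerateBeadsError(
            f"need at least {n_min} beads for this fit in {d}D, got {n}")

    mu_x = x.mean(axis=0)
    mu_y = y.mean(axis=0)
    xc = x - mu_x
    yc = y - mu_y
    var_x = float(np.mean(np.sum(xc**2, axis=1)))
    if var_x <= 0:
        raise DegenerateBeadsError("all source beads coincide")

    if allow_rotation:
        _check_rank(xc, d)
        cov = (yc.T @ xc) / n
        u, sv, vt = np.linalg.svd(cov)
        if np.linalg.det(u) * np.linalg.det(vt) < 0:
            raise ReflectionError(
                "optimal orthogonal matrix is a reflection (det = -1); "
                "check bead correspondence / handedness")
        rot = u @ vt
        scale = float(np.sum(sv)) / var_x if allow_scale else 1.0
    else:
        rot = np.eye(d)
        scale = float(np.sum(xc * yc)) / (n * var_x) if allow_scale else 1.0
        if allow_scale and scale <= 0:
            raise DegenerateBeadsError(
                "scale-only fit produced a non-positive scale")

    t = mu_y - scale * rot @ mu_x
    tf = SimilarityTransform(rot, scale, t)
    residuals = y - tf.apply(x)
    rmsd = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return RegistrationResult(transform=tf, rmsd=rmsd, n_beads=n,
                              residuals=residuals)


def apply_transform(transform: SimilarityTransform,
                    points: np.ndarray) -> np.ndarray:
    """Apply ``p -> s R p + t`` to an (n, d) array of points."""
    return transform.apply(points)


def estimate_scaling_factor(src, dst) -> float:
    """Isotropic scale between two bead sets, rotation disabled.

    Models the fixed-geometry integrated-FM workflow where FM images are
    overlaid on SEM images by pure scaling (plus translation).
    """
    res = fit_similarity(src, dst, allow_rotation=False, allow_scale=True)
    return res.transform.scale


def average_scaling_factor(scenes: Sequence[tuple]) -> tuple[float, float, np.ndarray]:
    """Mean +/- sample SD of the scaling factor over multiple bead scenes.

    ``scenes`` is a sequence of (src, dst) pairs; returns
    ``(mean, sd, per_scene_scales)``.
    """
    if len(scenes) < 1:
        raise ValueError("need at least one scene")
    scales = np.array([estimate_scaling_factor(s, d) for s, d in scenes])
    sd = float(np.std(scales, ddof=1)) if len(scales) > 1 else 0.0
    return float(np.mean(scales)), sd, scales


def leave_one_out(src, dst, allow_rotation: bool = True,
                  allow_scale: bool = True) -> LOOResult:
    """Leave-one-out localization errors of the bead registration.

    For each bead i the transform is refitted on the remaining beads, bead i
    is predicted, and the deviation ``dst_i - prediction`` recorded.  The
    per-axis sample SD (divisor n - 1) of these deviations is the accuracy
    estimate.
    """
    x, y, units = _matched_arrays(src, dst)
    n, d = x.shape
    n_min = (3 if d == 2 else 4) if allow_rotation else 2
    if n < n_min + 1:
        raise DegenerateBeadsError(
            f"leave-one-out needs at least {n_min + 1} beads, got {n}")
    errors = np.empty((n, d))
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        res = fit_similarity(x[keep], y[keep], allow_rotation=allow_rotation,
                             allow_scale=allow_scale)
        errors[i] = y[i] - res.transform.apply(x[i])
        keep[i] = True
    sds = np.std(errors, axis=0, ddof=1)
    return LOOResult(per_bead_errors=errors, sds=sds, n=n, units=units)
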