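"""Synthetic ground-truth data: helical lattices, wedge, noise, beads, cohorts.

This module generates the inputs the measurement pipeline assumes, with known
ground truth:

* ideal n-start helical lattices of Gaussian blobs on a cylinder (a
  microtubule without seam or supertwist), rendered into a
  :class:`~mtlattice.volume.TomogramVolume`;
* the tomographic missing wedge, applied as a hard binary mask in Fourier
  space about a chosen tilt axis (default tilt range +/-60 deg; instrument
  ranges in the modelled experiments span +/-45-63 deg);
* additive white Gaussian noise (no CTF / detector model);
* fiducial-bead scenes related by a known similarity transform with
  Gaussian localization noise, for exercising the registration fits;
* two-group lattice-spacing cohorts drawn from normals and snapped to the
  discrete reciprocal-space grid of the analysis box, for exercising the
  permutation statistics.

All stochastic functions are pure in (inputs, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .registration import BeadSet, SimilarityTransform
from .volume import TomogramVolume

__all__ = [
    "LatticeSpec",
    "generate_lattice_points",
    "render_volume",
    "apply_missing_wedge",
    "add_noise",
    "sigma_for_projection_snr",
    "make_bead_scene",
    "make_spacing_cohorts",
    "simulate_filament_volume",
]


@dataclass
class LatticeSpec:
    """Geometry of one ideal helical (microtubule-like) lattice.

    ``monomer_spacing`` is the axial repeat ``a`` along one protofilament in
    Å.  Protofilament ``p`` sits at azimuth ``p * 360 / n_pf`` on a cylinder
    of the given radius, staggered axially by ``p * n_start * a / n_pf``
    (the helical rise per subunit times p).  The default radius 105 Å is
    the density mid-wall of a 25-nm microtubule; blob_sigma 12 Å gives a
    realistic filament width at ~2-4 Å voxels without atomic detail.
    """

    monomer_spacing: float
    length: float
    n_pf: int = 13
    n_start: int = 3
    radius: float = 105.0
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    blob_sigma: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_pf) != self.n_pf or self.n_pf < 8:
            raise ValueError(f"n_pf: must be an integer >= 8, got {self.n_pf}")
        if int(self.n_start) != self.n_start or not (1 <= self.n_start <= self.n_pf):
            raise ValueError(
                f"n_start: must be an integer in [1, n_pf], got {self.n_start}")
        if not self.monomer_spacing > 0:
            raise ValueError(
                f"monomer_spacing: must be > 0, got {self.monomer_spacing}")
        if not self.radius > 0:
            raise ValueError(f"radius: must be > 0, got {self.radius}")
        if not self.length >= 2 * self.monomer_spacing:
            raise ValueError(
                f"length: must be >= 2 * monomer_spacing, got {self.length}")
        if not self.blob_sigma > 0:
            raise ValueError(f"blob_sigma: must be > 0, got {self.blob_sigma}")
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        if self.axis_origin.shape != (3,) or self.axis_direction.shape != (3,):
            raise ValueError("axis_origin/axis_direction: expected 3-vectors")
        nrm = np.linalg.norm(self.axis_direction)
        if not nrm > 0:
            raise ValueError("axis_direction: zero vector")
        self.axis_direction = self.axis_direction / nrm

    @property
    def rise(self) -> float:
        """Axial rise per subunit step, ``n_start * a / n_pf`` (Å)."""
        return self.n_start * self.monomer_spacing / self.n_pf


def _axis_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair perpendicular to ``direction``."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, direction)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def generate_lattice_points(spec: LatticeSpec):
    """Monomer positions of the ideal lattice, with (pf, monomer) metadata.

    Returns a pandas DataFrame with columns ``pf``, ``monomer``, ``x``,
    ``y``, ``z`` (Å).  Monomer (p, j) sits at axial coordinate
    ``j * a + p * n_start * a / n_pf`` and azimuth ``p * 360 / n_pf`` on the
    cylinder, rigidly mapped onto the spec's axis.  The point count is
    ``n_pf * floor(length / a)``.
    """
    import pandas as pd

    a = spec.monomer_spacing
    n_mon = int(np.floor(spec.length / a))
    p_idx = np.repeat(np.arange(spec.n_pf), n_mon)
    j_idx = np.tile(np.arange(n_mon), spec.n_pf)
    theta = 2 * np.pi * p_idx / spec.n_pf
    axial = j_idx * a + p_idx * spec.rise
    e1, e2 = _axis_frame(spec.axis_direction)
    pos = (spec.axis_origin[None, :]
           + spec.radius * np.cos(theta)[:, None] * e1[None, :]
           + spec.radius * np.sin(theta)[:, None] * e2[None, :]
           + axial[:, None] * spec.axis_direction[None, :])
    return pd.DataFrame({
        "pf": p_idx, "monomer": j_idx,
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
    })


def render_volume(points, voxel_size: float, dims: Sequence[int],
                  blob_sigma: float,
                  origin: Sequence[float] = (0.0, 0.0, 0.0)) -> TomogramVolume:
    """Render points as a sum of unit-amplitude isotropic Gaussian blobs.

    ``points`` is an (n, 3) array in Å (or a DataFrame with x/y/z columns).
    Rendering is additive (linear in the point list).  Points outside the
    physical extent of the grid are dropped with a warning.
    """
    if not voxel_size > 0:
        raise ValueError(f"voxel_size: must be > 0, got {voxel_size}")
    if not blob_sigma > 0:
        raise ValueError(f"blob_sigma: must be > 0, got {blob_sigma}")
    if hasattr(points, "columns"):
        points = points[["x", "y", "z"]].to_numpy()
    points = np.asarray(points, dtype=float)
    dims = tuple(int(n) for n in dims)
    origin = np.asarray(origin, dtype=float)

    vox = (points - origin) / voxel_size
    inside = np.all((vox >= 0) & (vox < np.asarray(dims)), axis=1)
    if not np.all(inside):
        warnings.warn(f"render_volume: dropping {int(np.sum(~inside))} "
                      "point(s) outside the grid extent")
        vox = vox[inside]

    sigma_vox = blob_sigma / voxel_size
    cut = int(np.ceil(4 * sigma_vox))
    vol = np.zeros(dims)
    for cx, cy, cz in vox:
        sl, gs = [], []
        for c, n in zip((cx, cy, cz), dims):
            i0 = max(0, int(np.ceil(c - cut)))
            i1 = min(n - 1, int(np.floor(c + cut)))
            idx = np.arange(i0, i1 + 1)
            sl.append(slice(i0, i1 + 1))
            gs.append(np.exp(-((idx - c) ** 2) / (2 * sigma_vox**2)))
        vol[sl[0], sl[1], sl[2]] += (gs[0][:, None, None]
                                     * gs[1][None, :, None]
                                     * gs[2][None, None, :])
    return TomogramVolume(vol, voxel_size, origin)


def apply_missing_wedge(volume: TomogramVolume, tilt_min_deg: float = -60.0,
                        tilt_max_deg: float = 60.0,
                        tilt_axis: str = "y") -> TomogramVolume:
    """Zero the Fourier region not sampled by a limited tilt range.

    The beam is the z axis; tilting about ``tilt_axis`` (x or y) through
    angles in [tilt_min, tilt_max] samples, by the central-slice theorem,
    the set of planes whose in-(u, z) angle psi satisfies
    ``-psi in [tilt_min, tilt_max] (mod 180)``, where u is the in-plane
    axis perpendicular to the tilt axis.  Everything else (the "missing
    wedge", centred on the k_z axis) is set to zero with a hard binary
    mask, making the operation an idempotent, non-expansive projection.
    """
    if tilt_axis not in ("x", "y"):
        raise ValueError(f"tilt_axis: must be 'x' or 'y', got {tilt_axis!r}")
    if not (-90 <= tilt_min_deg < tilt_max_deg <= 90):
        raise ValueError("degenerate tilt range: need "
                         f"-90 <= tilt_min < tilt_max <= 90, got "
                         f"({tilt_min_deg}, {tilt_max_deg})")
    t_ax = {"x": 0, "y": 1}[tilt_axis]
    u_ax = 1 - t_ax
    shape = volume.shape
    ku = np.fft.fftfreq(shape[u_ax])[:, None]
    kz = np.fft.fftfreq(shape[2])[None, :]
    # canonicalise the sign of (ku, kz) so +k and -k get bit-identical
    # angles: the mask must be exactly Hermitian for a real output
    flip = (kz < 0) | ((kz == 0) & (ku < 0))
    sgn = np.where(flip, -1.0, 1.0)
    psi = np.degrees(np.arctan2(sgn * kz, sgn * ku))
    centre = -(tilt_min_deg + tilt_max_deg) / 2
    half = (tilt_max_deg - tilt_min_deg) / 2
    dev = (psi - centre + 90.0) % 180.0 - 90.0  # fold mod 180 about centre
    keep2 = np.abs(dev) <= half + 1e-9
    keep2 |= (ku == 0) & (kz == 0)  # tilt-axis line: always sampled
    # Nyquist bins stand for +/-0.5 simultaneously and have no unambiguous
    # tilt angle; AND with the point reflection makes the mask exactly
    # Hermitian (binary), so the output is real and the map a projection
    nu, nz_ = keep2.shape
    refl = keep2[np.ix_((-np.arange(nu)) % nu, (-np.arange(nz_)) % nz_)]
    keep2 &= refl
    keep = np.expand_dims(keep2, axis=t_ax)
    spec = np.fft.fftn(volume.densities)
    spec *= keep
    out = np.fft.ifftn(spec).real
    return volume.copy_with(out)


def add_noise(volume: TomogramVolume, sigma: float,
              seed: Optional[int] = None) -> TomogramVolume:
    """Additive zero-mean Gaussian noise, reproducible for a fixed seed."""
    if sigma < 0:
        raise ValueError(f"sigma: must be >= 0, got {sigma}")
    if sigma == 0:
        return volume.copy_with(volume.densities.copy())
    if seed is None:
        raise ValueError("seed: required when sigma > 0")
    rng = np.random.default_rng(seed)
    noisy = volume.densities + rng.normal(0.0, sigma, volume.shape)
    return volume.copy_with(noisy)


def sigma_for_projection_snr(volume: TomogramVolume, target_snr: float) -> float:
    """Voxel-noise sigma giving a target variance SNR in the z projection.

    The segment images analysed downstream are sums over the volume z axis.
    Summing nz voxels of independent noise gives projected-noise variance
    ``nz * sigma**2``; defining image SNR as var(clean projection) /
    var(projected noise) and solving for sigma gives
    ``sigma = sqrt(var(proj) / (snr * nz))``.
    """
    if not target_snr > 0:
        raise ValueError(f"target_snr: must be > 0, got {target_snr}")
    proj = volume.densities.sum(axis=2)
    return float(np.sqrt(proj.var() / (target_snr * volume.shape[2])))


def make_bead_scene(n_beads: int, transform: SimilarityTransform,
                    noise_sd: float, field_of_view, seed: int
                    ) -> tuple[BeadSet, BeadSet]:
    """Matched fiducial-bead scene: ``dst = T(src) + N(0, noise_sd)``.

    Source positions are uniform in ``[0, field_of_view]`` per axis
    (scalar or per-axis extents).  Returns (src, dst) BeadSets with matched
    ids.
    """
    if n_beads < 3:
        raise ValueError(f"n_beads: need >= 3 for downstream fitting, "
                         f"got {n_beads}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd: must be >= 0, got {noise_sd}")
    d = transform.dims
    fov = np.broadcast_to(np.asarray(field_of_view, dtype=float), (d,))
    if not np.all(fov > 0):
        raise ValueError("field_of_view: extents must be > 0")
    rng = np.random.default_rng(seed)
    src = rng.uniform(0.0, 1.0, (n_beads, d)) * fov
    dst = transform.apply(src)
    if noise_sd > 0:
        dst = dst + rng.normal(0.0, noise_sd, (n_beads, d))
    ids = [f"b{i:03d}" for i in range(n_beads)]
    return (BeadSet(ids, src, space="src"),
            BeadSet(list(ids), dst, space="dst"))


def make_spacing_cohorts(mean_a: float, sd_a: float, n_a: int,
                         mean_b: float, sd_b: float, n_b: int,
                         grid: Optional[np.ndarray] = None,
                         seed: Optional[int] = None,
                         snap: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Two lattice-spacing cohorts (Å) on the discrete reciprocal grid.

    Values are drawn from N(mean, sd) per group and, by default, snapped to
    the nearest value of ``grid`` — the attainable spacings of the analysis
    box (defaults to the 2,235.1 Å physical edge, i.e. 1,030 px at
    2.17 Å/px, over 36-48 Å).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError(f"cohort sizes must be >= 2, got {n_a}, {n_b}")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    a = rng.normal(mean_a, sd_a, n_a)
    b = rng.normal(mean_b, sd_b, n_b)
    if snap:
        if grid is None:
            from .layerline import spacing_grid
            grid = spacing_grid(2.17, 1030, 36.0, 48.0)
        grid = np.sort(np.asarray(grid, dtype=float))
        a = _snap(a, grid)
        b = _snap(b, grid)
    return a, b


def _snap(values: np.ndarray, sorted_grid: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(sorted_grid, values)
    idx = np.clip(idx, 1, len(sorted_grid) - 1)
    lo = sorted_grid[idx - 1]
    hi = sorted_grid[idx]
    return np.where(values - lo <= hi - values, lo, hi)


def lattice_axial_extent(spec: LatticeSpec) -> float:
    """Axial distance (Å) between the first and last monomer centres."""
    n_mon = int(np.floor(spec.length / spec.monomer_spacing))
    return (n_mon - 1) * spec.monomer_spacing + (spec.n_pf - 1) * spec.rise


def centered_filament_spec(monomer_spacing: float, dims: Sequence[int],
                           voxel_size: float, margin_A: float = 24.0,
                           **kwargs) -> LatticeSpec:
    """Largest lattice along +y that fits the grid with a clear margin.

    Chooses the monomer count so that every monomer centre (including the
    protofilament stagger at the top) stays ``margin_A`` inside the y
    extent, and centres the filament in the grid.  Extra LatticeSpec fields
    pass through ``kwargs``.
    """
    a = monomer_spacing
    n_pf = kwargs.get("n_pf", 13)
    n_start = kwargs.get("n_start", 3)
    rise = n_start * a / n_pf
    phys = np.asarray(dims, dtype=float) * voxel_size
    avail = phys[1] - 2 * margin_A - (n_pf - 1) * rise
    n_mon = int(np.floor(avail / a)) + 1
    if n_mon < 2:
        raise ValueError("grid too small for two monomers per protofilament")
    spec = LatticeSpec(monomer_spacing=a, length=(n_mon + 0.5) * a, **kwargs)
    extent = lattice_axial_extent(spec)
    spec.axis_origin = np.array([phys[0] / 2, (phys[1] - extent) / 2,
                                 phys[2] / 2])
    return spec


def simulate_filament_volume(spec: LatticeSpec, dims: Sequence[int],
                             voxel_size: float,
                             origin: Sequence[float] = (0.0, 0.0, 0.0),
                             backbone_step: float = 40.0):
    """Render a lattice and return (volume, backbone FilamentModel).

    The backbone is the known filament axis sampled every ``backbone_step``
    Å from the first to the last monomer centre, expressed in 0-based voxel
    coordinates — the ground-truth analogue of a traced microtubule model.
    """
    from .layerline import FilamentModel

    pts = generate_lattice_points(spec)
    vol = render_volume(pts, voxel_size, dims, spec.blob_sigma, origin)
    span = lattice_axial_extent(spec)
    arc = np.arange(0.0, span + 1e-9, backbone_step)
    if arc[-1] < span:
        arc = np.concatenate([arc, [span]])
    axis_pts = (spec.axis_origin[None, :]
                + arc[:, None] * spec.axis_direction[None, :])
    bb_vox = (axis_pts - np.asarray(origin, dtype=float)) / voxel_size
    return vol, FilamentModel(points=bb_vox, voxel_size=voxel_size,
                              filament_id="synthetic")
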