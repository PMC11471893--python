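"""Fourier layer-line measurement of filament lattice spacing.

The axial repeat of a helical filament (the tubulin monomer spacing, ~41 Å
compacted / ~42+ Å expanded for microtubules) appears in the Fourier
transform of a filament image as a pair of layer lines at axial frequency
1/a.  The pipeline implemented here measures it directly from a tomogram:

1. resample the traced backbone at even arc-length steps;
2. build a soft cylindrical mask around the filament to suppress
   surrounding material;
3. tile the filament with square analysis boxes with minimal overlap;
4. for each box, resample the masked volume so the filament axis is the
   image vertical and sum along the original viewing (z) axis;
5. compute each segment's 2D power spectrum;
6. sum the power spectra of all segments of one filament, take a meridional
   line profile, and locate the equator and layer-line maxima.

The lattice spacing follows from the discrete peak offset:

    spacing = pixel_size * box / |equator_loc - layerline_loc|

so attainable spacings form the discrete grid {pixel_size * box / k}.  The
profile's signal-to-noise ratio is summarised as mean(signal)^2 /
std(signal)^2 (population std).

Conventions: 0-based voxel indices; centred FFT with the origin at index
``box // 2`` (exact for even and odd boxes alike); the filament axis maps
to image axis 0 ("vertical"), so layer lines are rows offset from the
equator row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume import TomogramVolume

__all__ = [
    "FilamentModel",
    "SegmentImage",
    "PowerSpectrumSum",
    "LayerLineProfile",
    "LatticeMeasurement",
    "MeasureConfig",
    "LayerLineNotFoundError",
    "resample_backbone",
    "make_filament_mask",
    "tile_segments",
    "extract_aligned_segment",
    "power_spectrum",
    "sum_power_spectra",
    "meridional_profile",
    "locate_layerline",
    "lattice_spacing_from_peaks",
    "profile_snr",
    "classify_spacing",
    "spacing_grid",
    "measure_filament",
]


class LayerLineNotFoundError(RuntimeError):
    """No detectable layer line: the filament is unmeasurable."""


# ---------------------------------------------------------------------------
# domain types

@dataclass
class FilamentModel:
    """Ordered backbone of one filament, 0-based voxel coordinates."""

    points: np.ndarray
    voxel_size: float
    filament_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points: expected (n, 3) array")
        if len(self.points) < 2:
            raise ValueError("points: need >= 2 backbone points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points: non-finite coordinates")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("points: consecutive points must be distinct")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size: must be > 0, got {self.voxel_size}")

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (voxels) at each backbone point."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Total polyline arc length in voxels."""
        return float(self.arc_lengths[-1])

    def point_at(self, s) -> np.ndarray:
        """Interpolate position(s) at arc length(s) ``s`` (voxels)."""
        cum = self.arc_lengths
        s = np.asarray(s, dtype=float)
        return np.stack([np.interp(s, cum, self.points[:, k])
                         for k in range(3)], axis=-1)

    @property
    def mean_direction(self) -> np.ndarray:
        """Unit end-to-end direction (filaments are straight in v1)."""
        d = self.points[-1] - self.points[0]
        return d / np.linalg.norm(d)


@dataclass
class SegmentImage:
    """One projected, axis-aligned filament segment (box x box pixels)."""

    pixels: np.ndarray
    pixel_size: float
    center: np.ndarray
    filament_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if (self.pixels.ndim != 2
                or self.pixels.shape[0] != self.pixels.shape[1]):
            raise ValueError("pixels: expected a square 2D image")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size: must be > 0, got {self.pixel_size}")
        self.center = np.asarray(self.center, dtype=float)

    @property
    def box(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PowerSpectrumSum:
    """Sum of per-segment 2D power spectra for one filament."""

    values: np.ndarray
    n_summed: int
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("values: power spectra are non-negative")
        if self.n_summed < 1:
            raise ValueError("n_summed: must be >= 1")

    @property
    def box(self) -> int:
        return self.values.shape[0]


@dataclass
class LayerLineProfile:
    """Meridional 1D profile of a summed power spectrum.

    ``signal[r]`` is the mean power over columns within
    ``+/-lateral_halfwidth`` of the meridian at axial-frequency row r.
    """

    signal: np.ndarray
    lateral_halfwidth: int
    pixel_size: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise ValueError("signal: expected a 1D profile")
        if np.any(self.signal < 0):
            raise ValueError("signal: must be non-negative")

    @property
    def box(self) -> int:
        return len(self.signal)


@dataclass
class LayerLineLocation:
    """Peak bookkeeping from :func:`locate_layerline`."""

    equator_loc: int
    layerline_locs: tuple          # detected peak rows, one per side used
    delta_px: float                # |equator - layer line|, averaged if 2-sided
    sides_used: tuple              # subset of ("upper", "lower")


@dataclass
class LatticeMeasurement:
    """Lattice-spacing result for one filament."""

    filament_id: str
    equator_loc: int
    layerline_locs: tuple
    delta_px: float
    spacing: float        # Å
    snr: float
    n_segments: int
    classification: str   # "compacted" or "expanded"

    def __post_init__(self) -> None:
        if not self.delta_px > 0:
            raise ValueError("delta_px: must be > 0")
        if not self.spacing > 0:
            raise ValueError("spacing: must be > 0")


@dataclass
class MeasureConfig:
    """Tunable parameters of :func:`measure_filament`.

    Defaults follow the full-resolution analysis: box 1,030 px at
    2.17 Å/px (2,235.1 Å physical edge).  Desk-scale runs may use 515 px at
    4.34 Å/px, which preserves the physical edge and therefore the identical
    spacing grid.
    """

    box: int = 1030
    overlap_frac: float = 0.1
    search_min_A: float = 38.0
    search_max_A: float = 46.0
    sides: str = "one"                 # "one" | "two"
    lateral_halfwidth: int = 10        # px about the meridian
    mask_radius_A: float = 180.0
    mask_soft_A: float = 40.0
    resample_step_vox: float = 5.0
    classify_threshold_A: float = 41.3
    detection_nmads: float = 3.0
    subpixel: bool = False             # 3-point parabolic refinement

    def __post_init__(self) -> None:
        if self.box < 4:
            raise ValueError("box: must be >= 4")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac: must be in [0, 1)")
        if self.sides not in ("one", "two"):
            raise ValueError("sides: must be 'one' or 'two'")
        if not self.search_min_A < self.search_max_A:
            raise ValueError("search band: need search_min_A < search_max_A")


# ---------------------------------------------------------------------------
# operations

def resample_backbone(points, step: float, voxel_size: float = 1.0,
                      filament_id: str = "") -> FilamentModel:
    """Resample a backbone polyline at even arc-length steps (voxels).

    Output points lie on the input polyline, spaced exactly ``step`` apart;
    the original endpoint is appended (closing gap < step) so the first and
    last input points are always preserved.
    """
    if isinstance(points, FilamentModel):
        filament_id = filament_id or points.filament_id
        voxel_size = points.voxel_size
        points = points.points
    model = FilamentModel(points, voxel_size, filament_id)
    if not step > 0:
        raise ValueError(f"step: must be > 0, got {step}")
    total = model.length
    if step > total:
        raise ValueError(f"step {step} exceeds polyline length {total}")
    n = int(np.floor(total / step + 1e-9))
    s = np.arange(n + 1) * step
    out = model.point_at(s)
    if total - s[-1] > 1e-9 * max(total, 1.0):
        out = np.vstack([out, model.points[-1]])
    return FilamentModel(out, voxel_size, filament_id)


def make_filament_mask(dims: Sequence[int], filament: FilamentModel,
                       radius: float = 180.0,
                       soft_width: float = 40.0) -> np.ndarray:
    """Soft cylindrical mask (values in [0, 1]) around the backbone.

    ``radius`` and ``soft_width`` are in Å.  The mask is 1 within ``radius``
    of the backbone polyline, 0 beyond ``radius + soft_width``, with a
    cosine taper between — monotone non-increasing in distance.  Distances
    are taken from a Euclidean distance transform of the densely rasterised
    backbone (accurate to ~half a voxel).
    """
    if not radius > 0:
        raise ValueError(f"radius: must be > 0, got {radius}")
    if soft_width < 0:
        raise ValueError(f"soft_width: must be >= 0, got {soft_width}")
    dims = tuple(int(n) for n in dims)
    vx = filament.voxel_size
    # rasterise the polyline densely so the EDT sees a connected curve
    dense = resample_backbone(filament, step=0.25)
    idx = np.round(dense.points).astype(int)
    idx = idx[np.all((idx >= 0) & (idx < np.asarray(dims)), axis=1)]
    if len(idx) == 0:
        raise ValueError("filament lies entirely outside the grid")
    seed = np.ones(dims, dtype=bool)
    seed[idx[:, 0], idx[:, 1], idx[:, 2]] = False
    dist = ndimage.distance_transform_edt(seed) * vx  # Å
    mask = np.zeros(dims)
    mask[dist <= radius] = 1.0
    if soft_width > 0:
        taper = (dist > radius) & (dist < radius + soft_width)
        mask[taper] = 0.5 * (1 + np.cos(np.pi * (dist[taper] - radius)
                                        / soft_width))
    return mask


def tile_segments(filament: FilamentModel, box: int,
                  overlap_frac: float = 0.1
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Segment centers covering the backbone with minimal overlap.

    Centers are spaced ``box * (1 - overlap_frac)`` voxels of arc length
    (shrunk evenly when the last box would overhang), so the union of
    box-long windows covers the full backbone extent; at least one segment
    is always returned.  Returns (centers (n, 3), unit tangents (n, 3)).
    """
    if not 0 <= overlap_frac < 1:
        raise ValueError(f"overlap_frac: must be in [0, 1), got {overlap_frac}")
    total = filament.length
    if total <= box:
        s = np.array([total / 2])
    else:
        stride = box * (1 - overlap_frac)
        n = int(np.ceil((total - box) / stride - 1e-9)) + 1
        s = np.linspace(box / 2, total - box / 2, n)
    centers = filament.point_at(s)
    d = filament.mean_direction
    tangents = np.tile(d, (len(s), 1))
    return centers, tangents


def extract_aligned_segment(volume: TomogramVolume,
                            mask: Optional[np.ndarray],
                            center: np.ndarray,
                            axis_direction: np.ndarray,
                            box: int,
                            depth: Optional[int] = None) -> SegmentImage:
    """Axis-aligned, z-projected segment image around ``center``.

    The (optionally masked) volume is resampled by trilinear interpolation
    into a box x box x depth block whose image axis 0 is the filament axis
    (in-plane component) and whose third axis is the original viewing (z)
    direction, then summed over depth.  Out-of-volume samples contribute 0.
    ``center`` is in 0-based voxel coordinates; ``depth`` defaults to the
    full z extent of the volume.
    """
    if box < 2:
        raise ValueError("box: must be >= 2")
    center = np.asarray(center, dtype=float)
    dims = np.asarray(volume.shape)
    if np.any(center < 0) or np.any(center >= dims):
        raise ValueError(f"center {center} outside volume of shape "
                         f"{tuple(dims)}")
    if depth is None:
        depth = volume.shape[2]
    if depth < 1:
        raise ValueError("depth: must be >= 1")
    a = np.asarray(axis_direction, dtype=float)
    a_xy = a.copy()
    a_xy[2] = 0.0
    nrm = np.linalg.norm(a_xy)
    if nrm < 1e-8:
        raise ValueError("axis_direction has no in-plane component; a "
                         "filament along the beam axis cannot be projected")
    e1 = a_xy / nrm                      # axial, in-plane
    e3 = np.array([0.0, 0.0, 1.0])       # original viewing direction
    e2 = np.cross(e3, e1)                # lateral, in-plane

    data = volume.densities if mask is None else volume.densities * mask
    half = box // 2
    i = np.arange(box) - half            # axial offset (image axis 0)
    j = np.arange(box) - half            # lateral offset (image axis 1)
    base = (center[None, None, :]
            + i[:, None, None] * e1[None, None, :]
            + j[None, :, None] * e2[None, None, :])
    img = np.zeros((box, box))
    for d_off in np.arange(depth) - depth // 2:
        pos = base + d_off * e3[None, None, :]
        img += ndimage.map_coordinates(
            data, [pos[..., 0], pos[..., 1], pos[..., 2]],
            order=1, mode="constant", cval=0.0)
    return SegmentImage(img, volume.voxel_size, center)


def power_spectrum(image) -> np.ndarray:
    """Centred 2D power spectrum |DFT|^2 (unnormalised-DFT convention).

    The origin sits at (box/2, box/2) (0-based); circular translations of
    the input leave the output unchanged; real input gives a point-
    symmetric spectrum.  Parseval: ``sum(ps) = box**2 * sum(image**2)``.
    """
    pixels = image.pixels if isinstance(image, SegmentImage) else np.asarray(image)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("power_spectrum: expected a square 2D image")
    return np.abs(np.fft.fftshift(np.fft.fft2(pixels))) ** 2


def sum_power_spectra(spectra: Sequence[np.ndarray],
                      pixel_size: float) -> PowerSpectrumSum:
    """Elementwise sum of same-shape power spectra (order-invariant)."""
    if len(spectra) == 0:
        raise ValueError("no spectra to sum")
    arrs = [np.asarray(s) for s in spectra]
    shape = arrs[0].shape
    for s in arrs[1:]:
        if s.shape != shape:
            raise ValueError(f"shape mismatch: {s.shape} vs {shape}")
    return PowerSpectrumSum(values=np.sum(arrs, axis=0),
                            n_summed=len(arrs), pixel_size=pixel_size)


def meridional_profile(ps_sum: PowerSpectrumSum,
                       lateral_halfwidth: int = 10) -> LayerLineProfile:
    """Mean power over the meridional band, per axial-frequency row."""
    box = ps_sum.box
    if lateral_halfwidth < 0 or lateral_halfwidth >= box // 2:
        raise ValueError(f"lateral_halfwidth: must be in [0, box/2), got "
                         f"{lateral_halfwidth}")
    c = box // 2
    band = ps_sum.values[:, c - lateral_halfwidth:c + lateral_halfwidth + 1]
    return LayerLineProfile(signal=band.mean(axis=1),
                            lateral_halfwidth=lateral_halfwidth,
                            pixel_size=ps_sum.pixel_size)


def _band_offsets(box: int, pixel_size: float, search_min_A: float,
                  search_max_A: float) -> np.ndarray:
    """Integer row offsets k with pixel_size*box/k inside the search band."""
    edge = pixel_size * box
    k_lo = int(np.ceil(edge / search_max_A - 1e-9))
    k_hi = int(np.floor(edge / search_min_A + 1e-9))
    k_lo = max(k_lo, 1)
    k_hi = min(k_hi, box // 2 - 1)
    if k_hi < k_lo:
        raise ValueError("search band contains no attainable offsets for "
                         f"box={box}, pixel_size={pixel_size}")
    return np.arange(k_lo, k_hi + 1)


def _refine_parabolic(signal: np.ndarray, row: int) -> float:
    """3-point parabolic sub-pixel peak refinement around ``row``."""
    if row <= 0 or row >= len(signal) - 1:
        return float(row)
    y0, y1, y2 = signal[row - 1:row + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(row)
    shift = 0.5 * (y0 - y2) / denom
    return row + float(np.clip(shift, -0.5, 0.5))


def locate_layerline(profile: LayerLineProfile,
                     search_min_A: float = 38.0,
                     search_max_A: float = 46.0,
                     sides: str = "one",
                     detection_nmads: float = 3.0,
                     subpixel: bool = False) -> LayerLineLocation:
    """Locate the equator and layer-line maxima in a meridional profile.

    The equator is the argmax within +/-2 rows of the geometric centre.
    On each requested side, the layer line is the argmax of the profile
    over the offsets whose spacing falls inside the search band
    (ties broken toward the smaller offset); a peak must exceed the band's
    local median + ``detection_nmads`` * MAD to count as detected.  In
    two-sided mode the per-side offsets are averaged (possibly yielding a
    half-integer delta); in one-sided mode the side with the stronger peak
    is used.

    Raises :class:`LayerLineNotFoundError` when no side has a detectable
    peak.
    """
    if sides not in ("one", "two"):
        raise ValueError("sides: must be 'one' or 'two'")
    sig = profile.signal
    box = profile.box
    c = box // 2
    eq_window = sig[c - 2:c + 3]
    equator = int(c - 2 + np.argmax(eq_window))
    ks = _band_offsets(box, profile.pixel_size, search_min_A, search_max_A)

    detected = {}
    for side, sgn in (("upper", +1), ("lower", -1)):
        rows = equator + sgn * ks
        valid = (rows >= 0) & (rows < box)
        if not np.any(valid):
            continue
        vals = sig[rows[valid]]
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        peak_i = int(np.argmax(vals))  # first max -> smaller offset wins ties
        if vals[peak_i] > med + detection_nmads * mad:
            k = float(ks[valid][peak_i])
            row = equator + sgn * k
            if subpixel:
                row_ref = _refine_parabolic(sig, int(row))
                k = abs(row_ref - equator)
                row = row_ref
            detected[side] = (row, k, vals[peak_i])

    if not detected:
        raise LayerLineNotFoundError(
            "no layer-line peak exceeds the local median + "
            f"{detection_nmads}*MAD detection threshold in "
            f"[{search_min_A}, {search_max_A}] Å")

    if sides == "one":
        side = max(detected, key=lambda s: detected[s][2])
        row, k, _ = detected[side]
        return LayerLineLocation(equator_loc=equator,
                                 layerline_locs=(row,),
                                 delta_px=k, sides_used=(side,))
    rows = tuple(detected[s][0] for s in ("upper", "lower") if s in detected)
    deltas = [detected[s][1] for s in ("upper", "lower") if s in detected]
    return LayerLineLocation(equator_loc=equator, layerline_locs=rows,
                             delta_px=float(np.mean(deltas)),
                             sides_used=tuple(detected))


def lattice_spacing_from_peaks(pixel_size: float, box: int, equator_loc: float,
                        layerline_loc: float) -> float:
    """Lattice spacing ``pixel_size * box / |equator - layer line|`` (Å)."""
    delta = abs(equator_loc - layerline_loc)
    if delta == 0:
        raise ValueError("equator and layer-line locations coincide")
    return pixel_size * box / delta


def profile_snr(signal) -> float:
    """Profile signal-to-noise ratio ``mean(signal)^2 / std(signal)^2``.

    The std uses divisor n (population).  Scale-invariant; undefined for a
    constant signal.
    """
    s = np.asarray(signal, dtype=float)
    if s.size < 2:
        raise ValueError("signal: need at least 2 values")
    var = s.var()  # population variance
    if var == 0:
        raise ValueError("signal is constant: SNR undefined (zero variance)")
    return float(s.mean() ** 2 / var)


def classify_spacing(spacing: float, threshold: float = 41.3) -> str:
    """"compacted" iff spacing < threshold, else "expanded" (right-closed).

    The default 41.3 Å is the midpoint of the gap between the compacted
    (40.8-41.1 Å) and expanded (41.5+ Å) bands.
    """
    return "compacted" if spacing < threshold else "expanded"


def spacing_grid(pixel_size: float, box: int, min_A: float, max_A: float,
                 half_steps: bool = False) -> np.ndarray:
    """Attainable spacings ``pixel_size * box / k`` within [min_A, max_A].

    k runs over integers (or half-integers when ``half_steps``); the result
    is sorted descending (increasing k).
    """
    if not min_A < max_A:
        raise ValueError(f"need min_A < max_A, got {min_A}, {max_A}")
    edge = pixel_size * box
    step = 0.5 if half_steps else 1.0
    k_lo = np.ceil(edge / max_A / step - 1e-9) * step
    k_hi = np.floor(edge / min_A / step + 1e-9) * step
    ks = np.arange(k_lo, k_hi + step / 2, step)
    ks = ks[ks > 0]
    return edge / ks


def measure_filament(volume: TomogramVolume, filament: FilamentModel,
                     config: Optional[MeasureConfig] = None
                     ) -> LatticeMeasurement:
    """Full layer-line measurement of one filament.

    Composition: resample backbone -> soft mask -> tile -> extract/project
    -> power spectra -> sum -> meridional profile -> peak location ->
    spacing.  The SNR is computed over the profile values inside the
    layer-line search band (both sides).  Propagates
    :class:`LayerLineNotFoundError` for unmeasurable filaments.
    """
    cfg = config or MeasureConfig()
    bb = resample_backbone(filament, step=cfg.resample_step_vox)
    mask = make_filament_mask(volume.shape, bb, radius=cfg.mask_radius_A,
                              soft_width=cfg.mask_soft_A)
    masked = volume.copy_with(volume.densities * mask)
    centers, tangents = tile_segments(bb, box=cfg.box,
                                      overlap_frac=cfg.overlap_frac)
    spectra = []
    for ctr, tng in zip(centers, tangents):
        seg = extract_aligned_segment(masked, None, ctr, tng, cfg.box)
        spectra.append(power_spectrum(seg))
    ps = sum_power_spectra(spectra, pixel_size=volume.voxel_size)
    prof = meridional_profile(ps, lateral_halfwidth=cfg.lateral_halfwidth)
    loc = locate_layerline(prof, cfg.search_min_A, cfg.search_max_A,
                           sides=cfg.sides,
                           detection_nmads=cfg.detection_nmads,
                           subpixel=cfg.subpixel)
    spacing = volume.voxel_size * cfg.box / loc.delta_px
    ks = _band_offsets(cfg.box, volume.voxel_size, cfg.search_min_A,
                       cfg.search_max_A)
    band_rows = np.concatenate([loc.equator_loc + ks, loc.equator_loc - ks])
    band_rows = band_rows[(band_rows >= 0) & (band_rows < prof.box)]
    snr = profile_snr(prof.signal[band_rows])
    return LatticeMeasurement(
        filament_id=filament.filament_id,
        equator_loc=loc.equator_loc,
        layerline_locs=loc.layerline_locs,
        delta_px=loc.delta_px,
        spacing=spacing,
        snr=snr,
        n_segments=ps.n_summed,
        classification=classify_spacing(spacing, cfg.classify_threshold_A),
    )
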