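"""Layer-line measurement tests: each pipeline stage plus end-to-end
invariants on synthetic lattices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtlattice import (FilamentModel, LatticeSpec, LayerLineNotFoundError,
                       LayerLineProfile, MeasureConfig, TomogramVolume,
                       classify_spacing, extract_aligned_segment,
                       generate_lattice_points, lattice_spacing_from_peaks,
                       locate_layerline, make_filament_mask, measure_filament,
                       meridional_profile, power_spectrum, render_volume,
                       resample_backbone, simulate_filament_volume, profile_snr,
                       spacing_grid, sum_power_spectra, tile_segments)
from mtlattice.layerline import PowerSpectrumSum

from conftest import SMALL_BOX, SMALL_DIMS, VOXEL


def straight_filament(n=2, length=100.0):
    pts = np.stack([np.full(11, 10.0), np.linspace(0, length, 11),
                    np.full(11, 10.0)], axis=1)
    return FilamentModel(pts, voxel_size=1.0, filament_id="f")


class TestResampleBackbone:
    def test_straight_line_counts(self):
        out = resample_backbone(straight_filament(), step=10.0)
        assert len(out.points) == 11
        assert np.allclose(np.diff(out.points[:, 1]), 10.0)

    def test_idempotent_on_evenly_spaced_input(self):
        f = straight_filament()
        out = resample_backbone(f, step=10.0)
        again = resample_backbone(out, step=10.0)
        assert np.allclose(out.points, again.points, atol=1e-6)

    def test_arc_length_conserved_and_endpoints_kept(self):
        pts = np.array([[0, 0, 0], [3, 4, 0], [3, 4, 5], [10, 4, 5.0]])
        f = FilamentModel(pts, 1.0)
        out = resample_backbone(f, step=2.5)
        assert np.allclose(out.points[0], pts[0])
        assert np.allclose(out.points[-1], pts[-1])
        assert abs(out.length - f.length) < 2.5

    def test_step_longer_than_polyline_rejected(self):
        with pytest.raises(ValueError):
            resample_backbone(straight_filament(), step=500.0)


class TestFilamentMask:
    def test_mask_values_by_distance(self):
        f = FilamentModel(np.array([[16.0, 4.0, 16.0], [16.0, 28.0, 16.0]]),
                          voxel_size=1.0)
        m = make_filament_mask((32, 32, 32), f, radius=5.0, soft_width=4.0)
        assert m[16, 16, 16] == 1.0                      # on the backbone
        assert m[16 + 4, 16, 16] == 1.0                  # inside radius
        assert m[16, 16, 16 + 12] == 0.0                 # beyond radius+soft
        mid = m[16 + 7, 16, 16]                          # in the taper
        assert 0.0 < mid < 1.0

    def test_monotone_in_distance(self):
        f = FilamentModel(np.array([[16.0, 4.0, 16.0], [16.0, 28.0, 16.0]]),
                          voxel_size=1.0)
        m = make_filament_mask((32, 32, 32), f, radius=3.0, soft_width=6.0)
        profile = m[16:, 16, 16]
        assert np.all(np.diff(profile) <= 1e-12)


class TestTileSegments:
    def test_filament_exactly_box_long_gives_one_center(self):
        f = straight_filament(length=100.0)
        centers, tangents = tile_segments(f, box=100, overlap_frac=0.1)
        assert len(centers) == 1
        assert np.allclose(centers[0], [10.0, 50.0, 10.0])
        assert np.allclose(tangents[0], [0, 1, 0])

    def test_two_segments_with_ten_percent_overlap(self):
        f = straight_filament(length=190.0)
        centers, _ = tile_segments(f, box=100, overlap_frac=0.1)
        assert len(centers) == 2
        gap = centers[1][1] - centers[0][1]
        assert gap == pytest.approx(90.0, abs=1e-9)  # boxes overlap 10 px

    @pytest.mark.parametrize("length", [100.0, 137.0, 260.0, 410.0])
    def test_every_backbone_point_covered(self, length):
        f = straight_filament(length=length)
        centers, _ = tile_segments(f, box=100, overlap_frac=0.1)
        y = np.linspace(0, length, 101)
        covered = np.zeros_like(y, dtype=bool)
        for c in centers:
            covered |= (y >= c[1] - 50 - 1e-9) & (y <= c[1] + 50 + 1e-9)
        assert covered.all()


class TestExtractAlignedSegment:
    def test_identity_rotation_equals_crop_and_project(self):
        rng = np.random.default_rng(0)
        data = rng.random((40, 40, 12))
        vol = TomogramVolume(data, 1.0)
        seg = extract_aligned_segment(vol, None, np.array([20.0, 20.0, 6.0]),
                                      np.array([0.0, 1.0, 0.0]), box=16,
                                      depth=12)
        # axis along +y: row i samples y = 12 + i, column j samples
        # x = 28 - j (lateral axis e2 = z cross y = -x), all of z
        x_idx = 28 - np.arange(16)
        y_idx = 12 + np.arange(16)
        ref = data[np.ix_(x_idx, y_idx)].sum(axis=2).T
        assert np.max(np.abs(seg.pixels - ref)) < 1e-3 * np.max(np.abs(ref))

    def test_vertical_autocorrelation_has_monomer_period(self, small_filament,
                                                         small_cfg):
        spec, vol, bb = small_filament
        centers, tangents = tile_segments(
            resample_backbone(bb, 5.0), SMALL_BOX, 0.1)
        seg = extract_aligned_segment(vol, None, centers[0], tangents[0],
                                      SMALL_BOX)
        col = seg.pixels - seg.pixels.mean(axis=0, keepdims=True)
        ac = np.fft.irfft(np.abs(np.fft.rfft(col, axis=0))**2, axis=0).sum(axis=1)
        period = spec.monomer_spacing / VOXEL          # ~9.45 voxels
        lo, hi = int(period * 0.6), int(period * 1.4)
        lag = lo + np.argmax(ac[lo:hi + 1])
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        lag_ref = lag + 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
        assert abs(lag_ref - period) <= 0.5

    def test_mask_removes_projected_density(self, small_filament):
        spec, vol, bb = small_filament
        bb2 = resample_backbone(bb, 5.0)
        centers, tangents = tile_segments(bb2, SMALL_BOX, 0.1)
        full = extract_aligned_segment(vol, None, centers[0], tangents[0],
                                       SMALL_BOX)
        tight = make_filament_mask(vol.shape, bb2,
                                   radius=0.5 * spec.radius, soft_width=0.0)
        cut = extract_aligned_segment(vol, tight, centers[0], tangents[0],
                                      SMALL_BOX)
        assert cut.pixels.sum() < 0.5 * full.pixels.sum()

    def test_center_outside_volume_rejected(self):
        vol = TomogramVolume(np.zeros((10, 10, 10)), 1.0)
        with pytest.raises(ValueError):
            extract_aligned_segment(vol, None, np.array([20.0, 5.0, 5.0]),
                                    np.array([0, 1.0, 0]), box=4)


class TestPowerSpectrum:
    def test_constant_image_energy_at_origin(self):
        ps = power_spectrum(np.full((16, 16), 3.0))
        assert ps[8, 8] == pytest.approx((3.0 * 256) ** 2)
        ps[8, 8] = 0
        assert np.all(ps < 1e-18 * (3.0 * 256) ** 2)

    def test_vertical_cosine_peaks_at_expected_rows(self):
        box, period = 64, 8
        rows = np.arange(box)
        img = np.cos(2 * np.pi * rows / period)[:, None] * np.ones((1, box))
        ps = power_spectrum(img)
        hot = np.argwhere(ps > ps.max() / 2)
        assert {tuple(h) for h in hot} == {(32 - 8, 32), (32 + 8, 32)}

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.random((32, 32))
        assert np.allclose(power_spectrum(img),
                           power_spectrum(np.roll(img, (5, -7), axis=(0, 1))),
                           rtol=1e-9, atol=1e-6)

    def test_parseval_unnormalized_convention(self):
        rng = np.random.default_rng(2)
        img = rng.random((24, 24))
        assert np.sum(power_spectrum(img)) == \
            pytest.approx(24**2 * np.sum(img**2))

    def test_point_symmetry_for_real_input(self):
        rng = np.random.default_rng(3)
        ps = power_spectrum(rng.random((16, 16)))
        flipped = ps[1:, 1:][::-1, ::-1]   # symmetry about (box/2, box/2)
        assert np.allclose(ps[1:, 1:], flipped, rtol=1e-9, atol=1e-6)


class TestSumAndProfile:
    def test_sum_identity_and_linearity(self):
        rng = np.random.default_rng(4)
        ps = power_spectrum(rng.random((16, 16)))
        one = sum_power_spectra([ps], pixel_size=1.0)
        assert one.n_summed == 1 and np.array_equal(one.values, ps)
        three = sum_power_spectra([ps, ps, ps], pixel_size=1.0)
        assert np.allclose(three.values, 3 * ps)

    def test_sum_order_invariant(self):
        rng = np.random.default_rng(5)
        spectra = [power_spectrum(rng.random((16, 16))) for _ in range(4)]
        a = sum_power_spectra(spectra, 1.0).values
        b = sum_power_spectra(spectra[::-1], 1.0).values
        assert np.allclose(a, b, rtol=1e-12, atol=0)

    def test_sum_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sum_power_spectra([np.ones((8, 8)), np.ones((10, 10))], 1.0)

    def test_profile_symmetric_for_symmetric_spectrum(self):
        rng = np.random.default_rng(6)
        ps = sum_power_spectra([power_spectrum(rng.random((32, 32)))], 1.0)
        prof = meridional_profile(ps, 4).signal
        assert np.allclose(prof[17:], prof[1:16][::-1], rtol=1e-9)

    def test_zero_halfwidth_is_meridian_column(self):
        vals = np.arange(256.0).reshape(16, 16)
        ps = PowerSpectrumSum(vals, 1, 1.0)
        assert np.array_equal(meridional_profile(ps, 0).signal, vals[:, 8])

    def test_impulse_rows_located(self):
        box = 64
        vals = np.zeros((box, box))
        vals[32 + 9, 32] = 5.0
        vals[32 - 9, 32] = 5.0
        prof = meridional_profile(PowerSpectrumSum(vals, 1, 1.0), 0).signal
        hot = set(np.argwhere(prof > 0).ravel())
        assert hot == {23, 41}


class TestLocateLayerline:
    def _profile_with_peak(self, box=1030, px=2.17, offsets=(53,),
                           base=1.0, peak=50.0):
        rng = np.random.default_rng(8)
        sig = base + 0.01 * rng.random(box)
        c = box // 2
        sig[c] = 1e6  # equator
        for off in offsets:
            sig[off if off < 0 else c + off] = peak
        return LayerLineProfile(sig, lateral_halfwidth=10, pixel_size=px)

    def test_single_peak_delta(self):
        prof = self._profile_with_peak(offsets=(53,))
        loc = locate_layerline(prof)
        assert loc.equator_loc == 515
        assert loc.delta_px == 53

    def test_two_sided_half_integer_average(self):
        box, c = 1030, 515
        prof = self._profile_with_peak(offsets=(53,))
        prof.signal[c - 54] = 50.0   # lower-side peak one row further out
        loc = locate_layerline(prof, sides="two")
        assert loc.delta_px == pytest.approx(53.5)
        assert set(loc.sides_used) == {"upper", "lower"}

    def test_flat_profile_raises(self):
        sig = np.ones(1030)
        sig[515] = 10.0
        with pytest.raises(LayerLineNotFoundError):
            locate_layerline(LayerLineProfile(sig, 10, 2.17))

    def test_tie_broken_toward_smaller_offset(self):
        prof = self._profile_with_peak(offsets=(53,))
        prof.signal[515 + 55] = prof.signal[515 + 53]
        loc = locate_layerline(prof)
        assert loc.delta_px == 53

    def test_offset_equator_tracked(self):
        prof = self._profile_with_peak(offsets=(53,))
        c = 1030 // 2
        prof.signal[c] = 1.0
        prof.signal[c + 2] = 1e6   # equator detected off-centre
        prof.signal[c + 2 + 53] = 80.0
        loc = locate_layerline(prof)
        assert loc.equator_loc == c + 2
        assert loc.delta_px == 53


class TestSpacingFormulaAndGrid:
    def test_printed_example(self):
        assert lattice_spacing_from_peaks(2.17, 1030, 515, 568) == \
            pytest.approx(2235.1 / 53)
        assert round(lattice_spacing_from_peaks(2.17, 1030, 515, 568), 3) == 42.172

    def test_nyquist_limit(self):
        assert lattice_spacing_from_peaks(2.0, 64, 32, 64) == pytest.approx(4.0)

    def test_binning_invariance(self):
        # same physical box edge -> identical spacing for the same delta
        assert lattice_spacing_from_peaks(4.34, 515, 257, 311) == \
            pytest.approx(lattice_spacing_from_peaks(2.17, 1030, 515, 569))

    def test_zero_delta_rejected(self):
        with pytest.raises(ValueError):
            lattice_spacing_from_peaks(2.17, 1030, 515, 515)

    def test_grid_printed_values(self):
        g = spacing_grid(2.17, 1030, 40, 44)
        assert np.allclose(np.round(g, 2), [43.83, 42.98, 42.17, 41.39, 40.64])

    def test_grid_strictly_decreasing(self):
        g = spacing_grid(2.17, 1030, 36, 48, half_steps=True)
        assert np.all(np.diff(g) < 0)

    @given(delta=st.integers(min_value=47, max_value=62))
    @settings(derandomize=True)
    def test_spacing_outputs_lie_on_grid_and_selfconsistent(self, delta):
        spacing = lattice_spacing_from_peaks(2.17, 1030, 515, 515 + delta)
        assert spacing * delta == pytest.approx(2.17 * 1030, abs=1e-9)
        g = spacing_grid(2.17, 1030, 30, 50)
        assert np.min(np.abs(g - spacing)) < 1e-9


class TestSnrEq2:
    def test_hand_computed_example(self):
        # mean 1.5, population variance 0.75 -> 2.25 / 0.75 = 3
        assert profile_snr([1, 1, 1, 3]) == pytest.approx(3.0)

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    @settings(derandomize=True)
    def test_scale_invariance(self, c):
        sig = np.array([1.0, 2.0, 5.0, 3.0])
        assert profile_snr(c * sig) == pytest.approx(profile_snr(sig), rel=1e-9)

    def test_offset_increases_snr(self):
        sig = np.array([1.0, 2.0, 5.0, 3.0])
        assert profile_snr(sig + 10.0) > profile_snr(sig)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            profile_snr([2.0, 2.0, 2.0])


class TestClassify:
    @pytest.mark.parametrize("spacing,expected", [
        (41.0, "compacted"), (41.9, "expanded"),
        (41.3, "expanded"),   # right-closed tie rule at the threshold
    ])
    def test_threshold_rule(self, spacing, expected):
        assert classify_spacing(spacing) == expected


class TestMeasureFilament:
    def test_small_lattice_measured_on_grid(self, small_filament, small_cfg):
        spec, vol, bb = small_filament
        m = measure_filament(vol, bb, small_cfg)
        grid = spacing_grid(VOXEL, SMALL_BOX, 38, 46)
        assert np.min(np.abs(grid - m.spacing)) < 1e-9
        # within one grid step of the true spacing (~1.6 Å at this box)
        assert abs(m.spacing - spec.monomer_spacing) <= 1.6
        assert m.classification in ("compacted", "expanded")
        assert m.n_segments >= 1 and m.snr > 0

    def test_axial_translation_invariance(self, small_cfg):
        spec = LatticeSpec(monomer_spacing=41.0, length=900.0,
                           axis_origin=(96 * VOXEL / 2, 120.0, 56 * VOXEL / 2))
        deltas = []
        for shift in (0.0, 7 * VOXEL):
            s = LatticeSpec(monomer_spacing=41.0, length=900.0,
                            axis_origin=spec.axis_origin + np.array([0, shift, 0]))
            vol, bb = simulate_filament_volume(s, SMALL_DIMS, VOXEL)
            deltas.append(measure_filament(vol, bb, small_cfg).delta_px)
        assert deltas[0] == deltas[1]

    @pytest.mark.parametrize("angle_deg", [0, 30, 45, 90])
    def test_inplane_rotation_invariance(self, angle_deg, small_cfg):
        dims = (224, 224, 72)
        phys = np.asarray(dims) * VOXEL
        th = np.radians(angle_deg)
        d = np.array([np.sin(th), np.cos(th), 0.0])
        length = 820.0
        origin = np.array([phys[0] / 2, phys[1] / 2, phys[2] / 2]) \
            - d * length / 2
        spec = LatticeSpec(monomer_spacing=41.0, length=length,
                           axis_origin=origin, axis_direction=d)
        vol, bb = simulate_filament_volume(spec, dims, VOXEL)
        m = measure_filament(vol, bb, small_cfg)
        expected = np.round(VOXEL * SMALL_BOX / 41.0)
        assert m.delta_px == expected

    def test_featureless_volume_raises(self, small_cfg):
        vol = TomogramVolume(np.zeros((64, 280, 32)), VOXEL)
        bb = FilamentModel(np.array([[32.0, 20.0, 16.0], [32.0, 260.0, 16.0]]),
                           VOXEL)
        with pytest.raises(LayerLineNotFoundError):
            measure_filament(vol, bb, small_cfg)

    def test_summing_particle_spectra_improves_profile_snr(
            self, small_filament):
        # summing power spectra of particles of the same structure with
        # independent noise flattens the background of the meridional
        # profile: the summed-spectrum SNR beats the single-particle SNR
        # (median over 20 noise seeds, at realistic cryo-ET image SNR ~0.1;
        # the statistic saturates once fluctuations are averaged down, so
        # the benefit is vs n = 1 rather than strictly per step)
        from mtlattice import (add_noise, make_filament_mask,
                               sigma_for_projection_snr)

        spec, vol, bb = small_filament
        bb2 = resample_backbone(bb, 5.0)
        mask = make_filament_mask(vol.shape, bb2, 180, 40)
        centers, tangents = tile_segments(bb2, SMALL_BOX, 0.1)
        sigma = sigma_for_projection_snr(vol, 0.1)
        edge = VOXEL * SMALL_BOX
        ks = np.arange(int(np.ceil(edge / 60)), int(np.floor(edge / 30)) + 1)
        c = SMALL_BOX // 2
        rows = np.concatenate([c + ks, c - ks])  # 30-60 Å plot window
        n_particles = 4
        snr_curves = []
        for s in range(20):
            spectra = []
            for i in range(n_particles):
                noisy = add_noise(vol, sigma, seed=1000 * s + i)
                masked = noisy.copy_with(noisy.densities * mask)
                spectra.append(power_spectrum(extract_aligned_segment(
                    masked, None, centers[0], tangents[0], SMALL_BOX)))
            snrs = []
            for n in range(1, n_particles + 1):
                ps = sum_power_spectra(spectra[:n], VOXEL)
                prof = meridional_profile(ps, 10)
                snrs.append(profile_snr(prof.signal[rows]))
            snr_curves.append(snrs)
        med = np.median(snr_curves, axis=0)
        assert np.all(med[1:] >= med[0])
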