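"""Gaussian shape matching, interpolation and peak-list assembly."""

import numpy as np
import pytest

from conftest import gauss
from nmfpeaks import (
    AxisCalibration,
    Peak,
    PeakList,
    Spectrum,
    adapt_linewidth,
    assemble_peaks,
    factorize,
    match_gaussian,
    parabolic_interpolate,
    pick_with_known_positions,
    preprocess,
)
from nmfpeaks.nmf import FactorPair
from nmfpeaks.peakpick import FWHM_PER_SIGMA, ComponentShape, ReferencingError


class TestMatchGaussian:
    def test_exact_gaussian_self_match(self):
        m = match_gaussian(gauss(64, 12.0, 2.0), avg_width=2.0)
        assert abs(m.center - 12.0) <= 0.5

    def test_taller_of_two_gaussians_wins(self):
        shape = gauss(64, 10, 2.0) + 0.999 * gauss(64, 30, 2.0)
        m = match_gaussian(shape, 2.0)
        assert abs(m.center - 10) <= 0.5

    def test_equal_pair_resolves_to_one_peak_not_between(self):
        # any perturbation decides toward the taller line; an (effectively)
        # equal pair must still land on one of the two apexes, never between
        shape = gauss(64, 20, 2.0) + gauss(64, 40, 2.0)
        m = match_gaussian(shape, 2.0)
        assert min(abs(m.center - 20), abs(m.center - 40)) <= 0.5
        for taller, other in ((20, 40), (40, 20)):
            shape = 1.001 * gauss(64, taller, 2.0) + gauss(64, other, 2.0)
            assert abs(match_gaussian(shape, 2.0).center - taller) <= 0.5

    def test_all_zero_shape_yields_no_peak_sentinel(self):
        assert match_gaussian(np.zeros(32), 2.0) is None

    def test_noisy_center_within_one_point(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            shape = gauss(64, 25.0, 2.0) + 0.05 * rng.uniform(0, 1, 64)
            m = match_gaussian(shape, 2.0)
            hits += abs(m.center - 25.0) <= 1.0
        assert hits == 100

    def test_2d_input_rejected(self):
        with pytest.raises(ValueError):
            match_gaussian(np.zeros((4, 4)))


class TestAdaptLinewidth:
    def test_exact_width_recovery(self):
        shape = ComponentShape(gauss(64, 20.0, 3.0))
        m0 = match_gaussian(shape, avg_width=2.0)
        m = adapt_linewidth(shape, m0)
        assert m.width == pytest.approx(3.0, abs=0.05)
        assert not m.at_bound

    def test_width_clamped_at_bound_with_flag(self):
        shape = ComponentShape(gauss(64, 20.0, 8.0))
        m0 = match_gaussian(shape, avg_width=2.0)
        m = adapt_linewidth(shape, m0, width_bounds=(0.5, 4.0))
        assert m.width == 4.0
        assert m.at_bound

    def test_noisy_width_within_three_tenths(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            shape = ComponentShape(gauss(64, 20.0, 2.5)
                                   + 0.05 * rng.uniform(0, 1, 64))
            m = adapt_linewidth(shape, match_gaussian(shape, 2.0))
            errs.append(abs(m.width - 2.5))
        assert np.median(errs) < 0.3


class TestParabolicInterpolate:
    @pytest.mark.parametrize("triple,expected", [
        ((1.0, 2.0, 1.0), (0.0, 2.0)),
        ((1.0, 4.0, 3.0), (0.25, 4.125)),
        ((2.0, 2.0, 2.0), (0.0, 2.0)),
        ((3.0, 4.0, 1.0), (-0.25, 4.125)),
    ])
    def test_matches_closed_form(self, triple, expected):
        off, height = parabolic_interpolate(*triple)
        assert off == pytest.approx(expected[0])
        assert height == pytest.approx(expected[1])

    def test_offset_bounded_and_height_dominates(self, rng):
        for _ in range(200):
            y0 = rng.uniform(1, 10)
            ym = rng.uniform(0, y0)
            yp = rng.uniform(0, y0)
            off, height = parabolic_interpolate(ym, y0, yp)
            assert -0.5 < off <= 0.5
            assert height >= y0 - 1e-12

    def test_non_maximum_triple_rejected(self):
        with pytest.raises(ValueError):
            parabolic_interpolate(5.0, 1.0, 0.0)


def _factor_pair_from_peaks(spectrum, centers, amps, width=2.0):
    n0, n1 = spectrum.shape
    A = np.column_stack([gauss(n0, c0, width) for c0, _ in centers])
    A /= A.sum(axis=0)
    scalefree = [np.outer(gauss(n0, c0, width), gauss(n1, c1, width))
                 for c0, c1 in centers]
    Yn, scale = preprocess(spectrum.data)
    X = np.stack([a * gauss(n1, c1, width) * gauss(n0, c0, width).sum() / scale
                  for (c0, c1), a in zip(centers, amps)])
    return FactorPair(A=A, X=X, scale=scale)


class TestAssemblePeaks:
    def _spectrum(self, hsqc_axes, centers, amps, width=2.0):
        y = sum(a * np.outer(gauss(64, c0, width), gauss(64, c1, width))
                for (c0, c1), a in zip(centers, amps))
        return Spectrum(y, hsqc_axes)

    def test_positions_and_intensities_recovered(self, hsqc_axes):
        centers = [(20.0, 18.0), (42.0, 45.0)]
        amps = [1.0, 0.5]
        s = self._spectrum(hsqc_axes, centers, amps)
        Yn, scale = preprocess(s.data)
        pair, _ = factorize(Yn, 2, seed=0, scale=scale)
        pl = assemble_peaks(pair, s, threshold=0.1)
        assert len(pl) == 2
        got = sorted((p.positions_points, p.intensity) for p in pl.peaks)
        for (pos, intensity), c, a in zip(got, centers, amps):
            np.testing.assert_allclose(pos, c, atol=0.1)
            assert intensity == pytest.approx(a, rel=0.02)

    def test_threshold_one_keeps_only_strongest(self, hsqc_axes):
        s = self._spectrum(hsqc_axes, [(20.0, 18.0), (42.0, 45.0)], [1.0, 0.5])
        Yn, scale = preprocess(s.data)
        pair, _ = factorize(Yn, 2, seed=0, scale=scale)
        pl = assemble_peaks(pair, s, threshold=1.0)
        assert len(pl) == 1
        np.testing.assert_allclose(pl.peaks[0].positions_points, (20, 18),
                                   atol=0.1)

    def test_zero_components_give_empty_list(self, hsqc_axes):
        s = Spectrum(np.zeros((64, 64)), hsqc_axes)
        pair = FactorPair(A=np.zeros((64, 2)), X=np.zeros((2, 64)), scale=1.0)
        assert len(assemble_peaks(pair, s)) == 0

    def test_intensity_homogeneous_in_spectrum_scale(self, hsqc_axes):
        centers = [(20.0, 18.0), (42.0, 45.0)]
        s1 = self._spectrum(hsqc_axes, centers, [1.0, 0.5])
        s2 = Spectrum(7.0 * s1.data, hsqc_axes)
        out = []
        for s in (s1, s2):
            Yn, scale = preprocess(s.data)
            pair, _ = factorize(Yn, 2, seed=0, scale=scale)
            pl = assemble_peaks(pair, s, threshold=0.1)
            out.append(sorted(p.intensity for p in pl.peaks))
        np.testing.assert_allclose(out[1], 7.0 * np.array(out[0]), rtol=1e-6)

    def test_ppm_positions_follow_axis_calibration(self, hsqc_axes):
        s = self._spectrum(hsqc_axes, [(20.0, 18.0)], [1.0])
        Yn, scale = preprocess(s.data)
        pair, _ = factorize(Yn, 1, seed=0, scale=scale)
        pl = assemble_peaks(pair, s, threshold=0.1)
        p = pl.peaks[0]
        for a in range(2):
            assert p.positions_ppm[a] == pytest.approx(
                hsqc_axes[a].point_to_ppm(p.positions_points[a]), abs=1e-9)

    def test_linewidths_reported_as_fwhm(self, hsqc_axes):
        s = self._spectrum(hsqc_axes, [(30.0, 30.0)], [1.0], width=2.0)
        Yn, scale = preprocess(s.data)
        pair, _ = factorize(Yn, 1, seed=0, scale=scale)
        pl = assemble_peaks(pair, s, threshold=0.1)
        for w in pl.peaks[0].linewidths:
            assert w == pytest.approx(2.0 * FWHM_PER_SIGMA, rel=0.05)


class TestPickWithKnownPositions:
    def _overlapped(self, hsqc_axes):
        # overlap on axis 0 (2-point separation), resolved on axis 1
        y = (1.0 * np.outer(gauss(64, 30, 2), gauss(64, 20, 2))
             + 0.7 * np.outer(gauss(64, 32, 2), gauss(64, 40, 2)))
        return Spectrum(y, hsqc_axes)

    def _known(self, axes, points):
        return PeakList(peaks=[
            Peak(positions_points=(pt, np.nan),
                 positions_ppm=(axes[0].point_to_ppm(pt), np.nan),
                 intensity=0.0, linewidths=(np.nan, np.nan))
            for pt in points])

    def test_free_axis_recovered_under_overlap(self, hsqc_axes):
        s = self._overlapped(hsqc_axes)
        pl = pick_with_known_positions(
            s, self._known(hsqc_axes, [30.0, 32.0]), known_axes=(0,), seed=0)
        assert len(pl) == 2
        by_comp = sorted(pl.peaks, key=lambda p: p.component_id)
        # constrained coordinate carried through (verbatim in ppm)
        assert by_comp[0].positions_ppm[0] == hsqc_axes[0].point_to_ppm(30.0)
        assert by_comp[0].positions_points[0] == pytest.approx(30.0, abs=1e-9)
        assert by_comp[0].positions_points[1] == pytest.approx(20.0, abs=0.2)
        assert by_comp[1].positions_points[1] == pytest.approx(40.0, abs=0.2)

    def test_empty_known_list_falls_back_with_warning(self, two_peak_spectrum):
        with pytest.warns(UserWarning, match="empty known-peak list"):
            pl = pick_with_known_positions(two_peak_spectrum, PeakList(),
                                           seed=0, r=2, threshold=0.1)
        assert len(pl) == 2

    def test_off_grid_position_names_axis(self, hsqc_axes):
        s = self._overlapped(hsqc_axes)
        bad = PeakList(peaks=[Peak(positions_points=(200.0, np.nan),
                                   positions_ppm=(np.nan, np.nan),
                                   intensity=0.0, linewidths=())])
        with pytest.raises(ReferencingError, match="axis 0"):
            pick_with_known_positions(s, bad, known_axes=(0,))

    def test_consistent_with_unconstrained_run(self, hsqc_axes):
        """Feeding an unconstrained run's positions back as known input
        reproduces the same peak list within tolerance."""
        s = self._overlapped(hsqc_axes)
        free = pick_with_known_positions(
            s, self._known(hsqc_axes, [30.0, 32.0]), known_axes=(0,), seed=0)
        again = pick_with_known_positions(
            s, self._known(hsqc_axes, [p.positions_points[0] for p in free.peaks]),
            known_axes=(0,), seed=1)
        got = sorted(p.positions_points[1] for p in again.peaks)
        want = sorted(p.positions_points[1] for p in free.peaks)
        np.testing.assert_allclose(got, want, atol=0.2)
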