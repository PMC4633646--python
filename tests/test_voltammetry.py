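import numpy as np
import pytest

from hemecat.constants import FARADAY
from hemecat.exceptions import BaselineWarning, PeakDetectionError
from hemecat.io import Reference, Voltammogram
from hemecat.synthetic import GeneratorSpec, simulate_surface_cv
from hemecat.voltammetry import (
    RedoxFeature,
    area_ratio,
    coverage_from_charge,
    find_onset,
    find_redox_feature,
    integrate_peak,
    onset_gap,
    split_branches,
    subtract_linear_baseline,
)

COVERAGE = 2.55e-12  # mol cm^-2, one-electron surface couple
Q_EXPECTED = FARADAY * 0.096 * COVERAGE  # ~2.36e-8 C


def _edge_windows(v, width=0.05):
    lo, hi = v.potential.min(), v.potential.max()
    return [(lo, lo + width), (hi - width, hi)]


def _clean_couple(e_half=-0.097, sep=0.070, noise=0.0, seed=0, coverage=COVERAGE):
    return simulate_surface_cv(
        e_half,
        coverage,
        1,
        2.0,
        spec=GeneratorSpec(seed=seed, noise_fraction=noise),
        peak_separation=sep,
    )


def _baseline_subtracted(v):
    wins = _edge_windows(v)
    cat, an = split_branches(v)
    cat_b = subtract_linear_baseline(cat, wins)
    an_b = subtract_linear_baseline(an, wins)
    return Voltammogram(
        np.concatenate([cat_b.potential, an_b.potential]),
        np.concatenate([cat_b.current, an_b.current]),
        v.scan_rate,
    )


class TestSubtractLinearBaseline:
    def test_pure_line_maps_to_zero(self):
        e = np.linspace(-0.4, 0.2, 200)
        v = Voltammogram(e, 3e-7 * e + 5e-8, scan_rate=1.0)
        out = subtract_linear_baseline(v, [(-0.4, -0.35), (0.15, 0.2)])
        np.testing.assert_allclose(out.current, 0.0, atol=1e-18)

    def test_gaussian_peak_on_line_leaves_flat_tails(self):
        e = np.linspace(-0.4, 0.2, 400)
        peak = 1e-6 * np.exp(-(((e + 0.1) / 0.02) ** 2))
        v = Voltammogram(e, peak + 2e-7 * e + 1e-7, scan_rate=1.0)
        out = subtract_linear_baseline(v, [(-0.4, -0.35), (0.15, 0.2)])
        tails = (e < -0.3) | (e > 0.1)
        assert np.abs(out.current[tails]).mean() < 0.01 * 1e-6
        # anchor-window residual means are ~0 by construction
        for lo, hi in [(-0.4, -0.35), (0.15, 0.2)]:
            m = (e >= lo) & (e <= hi)
            assert abs(out.current[m].mean()) < 1e-12 * 1e-6

    def test_windows_inside_peak_raise_warning(self):
        e = np.linspace(-0.4, 0.2, 400)
        peak = 1e-6 * np.exp(-(((e + 0.1) / 0.05) ** 2))
        v = Voltammogram(e, peak + 2e-7 * e, scan_rate=1.0)
        with pytest.warns(BaselineWarning):
            subtract_linear_baseline(v, [(-0.17, -0.13), (-0.07, -0.03)])

    def test_overlapping_windows_rejected(self):
        e = np.linspace(-0.4, 0.2, 100)
        v = Voltammogram(e, np.zeros_like(e), scan_rate=1.0)
        with pytest.raises(ValueError, match="overlap"):
            subtract_linear_baseline(v, [(-0.4, -0.2), (-0.3, -0.1)])

    def test_sparse_window_rejected(self):
        e = np.linspace(-0.4, 0.2, 100)
        v = Voltammogram(e, np.zeros_like(e), scan_rate=1.0)
        with pytest.raises(ValueError, match="need >= 3"):
            subtract_linear_baseline(v, [(-0.4001, -0.3999), (0.15, 0.2)])


class TestIntegratePeak:
    def test_rectangle_charge(self):
        e = np.linspace(0.0, 0.1, 101)
        v = Voltammogram(e, np.full_like(e, 1e-6), scan_rate=1.0)
        assert integrate_peak(v, (0.0, 0.1)) == pytest.approx(1e-7, rel=1e-6)

    def test_ideal_surface_peak_charge_is_nFAGamma(self):
        v = _clean_couple(sep=0.0)
        cat, _ = split_branches(v)
        cat_b = subtract_linear_baseline(cat, _edge_windows(v))
        q = integrate_peak(cat_b, (v.potential.min(), v.potential.max()))
        assert q == pytest.approx(Q_EXPECTED, rel=2e-3)

    @pytest.mark.parametrize("scan_rate", [0.1, 1.0, 2.0])
    def test_charge_invariant_to_scan_rate(self, scan_rate):
        v = simulate_surface_cv(
            -0.097,
            COVERAGE,
            1,
            scan_rate,
            spec=GeneratorSpec(seed=0, noise_fraction=0.0),
        )
        cat, _ = split_branches(v)
        cat_b = subtract_linear_baseline(cat, _edge_windows(v))
        q = integrate_peak(cat_b, (v.potential.min(), v.potential.max()))
        assert q == pytest.approx(Q_EXPECTED, rel=2e-3)

    def test_nonmonotonic_window_rejected(self):
        v = _clean_couple()
        with pytest.raises(ValueError, match="monotonic"):
            integrate_peak(v, (v.potential.min(), v.potential.max()))

    def test_empty_window_rejected(self):
        v = _clean_couple()
        with pytest.raises(ValueError, match="< 2 points"):
            integrate_peak(v, (5.0, 5.1))


class TestCoverageFromCharge:
    def test_recovers_printed_coverage(self, constants):
        res = coverage_from_charge(2.362e-8, 1, constants)
        assert res.coverage == pytest.approx(2.55e-12, rel=1e-3)
        assert res.moles_total == pytest.approx(res.coverage * 0.096)

    def test_zero_charge_gives_zero_coverage(self, constants):
        assert coverage_from_charge(0.0, 1, constants).coverage == 0.0

    def test_linearity_in_charge(self, constants):
        a = coverage_from_charge(1e-8, 1, constants).coverage
        b = coverage_from_charge(2e-8, 1, constants).coverage
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_zero_electrons_rejected(self, constants):
        with pytest.raises(ValueError):
            coverage_from_charge(1e-8, 0, constants)


class TestFindRedoxFeature:
    def test_quasireversible_couple_positions(self):
        # cathodic peak -132 mV, anodic -62 mV -> E1/2 -97 mV, dEp 70 mV
        v = _baseline_subtracted(_clean_couple(noise=0.002, seed=3))
        f = find_redox_feature(v)
        assert f.e_cathodic == pytest.approx(-0.132, abs=0.003)
        assert f.e_anodic == pytest.approx(-0.062, abs=0.003)
        assert f.e_half == pytest.approx(-0.097, abs=0.003)
        assert f.delta_ep == pytest.approx(0.070, abs=0.004)

    def test_symmetric_couple_has_zero_midpoint(self):
        v = _baseline_subtracted(_clean_couple(e_half=0.0, noise=0.002, seed=4))
        f = find_redox_feature(v)
        assert f.e_half == pytest.approx(0.0, abs=0.003)

    def test_single_branch_raises_detection_error(self):
        e = np.linspace(-0.4, 0.2, 300)
        i = -1e-6 * np.exp(-(((e + 0.1) / 0.03) ** 2))
        rng = np.random.default_rng(0)
        full = np.concatenate([i[::-1], 1e-9 * rng.normal(size=e.size)])
        v = Voltammogram(np.concatenate([e[::-1], e]), full, scan_rate=1.0)
        with pytest.raises(PeakDetectionError, match="anodic"):
            find_redox_feature(v)

    def test_invariant_under_potential_shift_and_current_scale(self):
        v = _baseline_subtracted(_clean_couple(noise=0.002, seed=5))
        f0 = find_redox_feature(v)
        shifted = Voltammogram(v.potential + 0.123, v.current * 7.5, v.scan_rate)
        f1 = find_redox_feature(shifted)
        assert f1.e_half - f0.e_half == pytest.approx(0.123, abs=1e-9)
        assert f1.delta_ep == pytest.approx(f0.delta_ep, abs=1e-9)


class TestAreaRatio:
    def _feature(self, q):
        return RedoxFeature(-0.13, -0.06, q, q)

    def test_identical_features_give_unity(self):
        assert area_ratio(self._feature(1e-8), self._feature(1e-8)) == 1.0

    def test_superposed_couples_double_the_charge(self):
        spec = GeneratorSpec(seed=0, noise_fraction=0.0)
        v_fe = simulate_surface_cv(
            -0.0575, COVERAGE, 1, 2.0, spec=spec, peak_separation=0.070,
            potential_range=(-0.45, 0.3),
        )
        # Cu loading adds a second one-electron couple overlapping the heme one
        v_cu = simulate_surface_cv(
            -0.097, 2 * COVERAGE, 1, 2.0, spec=spec, peak_separation=0.070,
            potential_range=(-0.45, 0.3),
        )
        wins = [(-0.45, -0.40), (0.25, 0.30)]

        def charge(v):
            cat, _ = split_branches(v)
            return integrate_peak(
                subtract_linear_baseline(cat, wins), (-0.45, 0.3)
            )

        ratio = charge(v_cu) / charge(v_fe)
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_printed_coverage_ratio(self):
        # charges proportional to the quoted coverages 2.55 and 4.65e-12
        f_fe = self._feature(2.55)
        f_cufe = self._feature(4.65)
        assert area_ratio(f_fe, f_cufe) == pytest.approx(1.82, abs=0.01)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            area_ratio(RedoxFeature(-0.1, -0.05, 0.0, 0.0), self._feature(1.0))


class TestOnset:
    def test_onset_gap_matches_shunt_argument(self):
        assert onset_gap(-0.263, -0.097) == pytest.approx(-0.166)

    def test_equal_inputs_give_zero(self):
        assert onset_gap(-0.1, -0.1) == 0.0

    def test_antisymmetry(self):
        assert onset_gap(-0.263, -0.097) == -onset_gap(-0.097, -0.263)

    def test_mixed_references_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            onset_gap(-0.263, -0.097, Reference.NHE, Reference.AgAgCl)

    def test_find_onset_on_sigmoidal_wave(self):
        e = np.linspace(-0.5, 0.1, 600)
        plateau = 1e-4
        i = -plateau / (1.0 + np.exp((e + 0.20) / 0.02))
        v = Voltammogram(e, i, scan_rate=0.1)
        e_on = find_onset(v, threshold=0.05)
        # 5% of plateau is reached at E = -0.20 + 0.02*ln(19)
        assert e_on == pytest.approx(-0.20 + 0.02 * np.log(19.0), abs=2e-3)


class TestCoverageRoundTrip:
    def test_simulated_coverage_recovered_within_2pct_at_1pct_noise(self, constants):
        errs = []
        for seed in range(5):
            v = _clean_couple(noise=0.01, seed=seed)
            cat, _ = split_branches(v)
            cat_b = subtract_linear_baseline(cat, _edge_windows(v))
            q = integrate_peak(cat_b, (v.potential.min(), v.potential.max()))
            gamma = coverage_from_charge(q, 1, constants).coverage
            errs.append(abs(gamma / COVERAGE - 1.0))
        assert np.median(errs) < 0.02
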