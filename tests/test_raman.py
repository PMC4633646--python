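import numpy as np
import pytest

from hemecat.exceptions import AmbiguousAssignmentError
from hemecat.raman import (
    BandAssignment,
    LorentzianComponent,
    assign_species,
    class_fractions,
    default_assignment_table,
    fit_mixture,
)
from hemecat.synthetic import GeneratorSpec, nu3_turnover_fixture, simulate_spectrum

NU3_WINDOW = (1440.0, 1545.0)
NU3_SEEDS = [1473.0, 1493.0, 1504.0, 1508.0]
NU3_BOXES = [(1469, 1477), (1489, 1497), (1502, 1506), (1506, 1510)]


def _fit_fixture(seed, noise=0.01):
    truth = nu3_turnover_fixture()
    s = simulate_spectrum(truth, GeneratorSpec(seed=seed, noise_fraction=noise))
    result = fit_mixture(
        s, NU3_WINDOW, NU3_SEEDS, center_windows=NU3_BOXES, fwhm_bounds=(3, 14)
    )
    return truth, result


class TestFitMixture:
    def test_noiseless_single_lorentzian_self_fit(self):
        truth = [LorentzianComponent(1493.0, 12.0, 1.0)]
        s = simulate_spectrum(truth, GeneratorSpec(seed=0, noise_fraction=0.0))
        r = fit_mixture(s, (1440, 1545), [1493.0])
        assert r.residual_rms < 1e-8
        assert r.components[0].center == pytest.approx(1493.0, abs=1e-6)
        assert r.components[0].fwhm == pytest.approx(12.0, abs=1e-6)
        assert r.components[0].height == pytest.approx(1.0, abs=1e-6)

    def test_two_overlapped_components_recovered(self):
        truth = [
            LorentzianComponent(1493.0, 12.0, 1.0),
            LorentzianComponent(1504.0, 12.0, 0.8),
        ]
        s = simulate_spectrum(truth, GeneratorSpec(seed=0, noise_fraction=0.02))
        r = fit_mixture(s, (1450, 1545), [1493.0, 1504.0])
        for fitted, true in zip(r.components, truth):
            assert abs(fitted.center - true.center) < 1.0
            assert abs(fitted.area / true.area - 1.0) < 0.10

    def test_four_component_turnover_region_recovered(self):
        truth, r = _fit_fixture(seed=0)
        for fitted, true in zip(r.components, truth):
            assert abs(fitted.center - true.center) < 1.5
            assert abs(fitted.area / true.area - 1.0) < 0.10

    def test_area_identity_for_fitted_components(self):
        _, r = _fit_fixture(seed=1)
        for comp in r.components:
            assert comp.area == pytest.approx(
                comp.height * np.pi * comp.fwhm / 2.0, rel=1e-6
            )

    def test_adding_present_component_never_worsens_residual(self):
        truth = nu3_turnover_fixture()
        s = simulate_spectrum(truth, GeneratorSpec(seed=2, noise_fraction=0.01))
        r3 = fit_mixture(
            s, NU3_WINDOW, NU3_SEEDS[:3], center_windows=NU3_BOXES[:3], fwhm_bounds=(3, 14)
        )
        r4 = fit_mixture(
            s, NU3_WINDOW, NU3_SEEDS, center_windows=NU3_BOXES, fwhm_bounds=(3, 14)
        )
        assert r4.residual_rms <= r3.residual_rms + 1e-12

    def test_seed_outside_window_rejected(self):
        s = simulate_spectrum(nu3_turnover_fixture(), GeneratorSpec(seed=0))
        with pytest.raises(ValueError, match="outside the fit window"):
            fit_mixture(s, NU3_WINDOW, [1600.0])

    def test_window_beyond_spectrum_rejected(self):
        s = simulate_spectrum(nu3_turnover_fixture(), GeneratorSpec(seed=0))
        with pytest.raises(ValueError, match="beyond the spectrum"):
            fit_mixture(s, (1000, 1545), [1493.0])

    def test_deterministic_given_identical_inputs(self):
        _, a = _fit_fixture(seed=3)
        _, b = _fit_fixture(seed=3)
        assert [c.center for c in a.components] == [c.center for c in b.components]
        assert a.residual_rms == b.residual_rms


class TestAssignment:
    def test_marker_band_class_assignments(self):
        table = default_assignment_table()
        result, labels = _assigned_fixture()
        assert labels == (
            "HS ferrous",
            "resting HS ferric",
            "LS ferric",
            "ferryl",
        )
        assert sum(result.fractions.values()) == pytest.approx(1.0)

    def test_class_fractions_aggregate(self):
        table = default_assignment_table()
        result, _ = _assigned_fixture()
        cf = class_fractions(result, table)
        assert set(cf) == {"HS-FeII", "HS-FeIII", "LS-FeIII", "FeIV=O"}
        assert sum(cf.values()) == pytest.approx(1.0)

    def test_component_outside_all_windows_is_unassigned(self):
        r = _manual_result([LorentzianComponent(1600.0, 10.0, 1.0)])
        out = assign_species(r, default_assignment_table())
        assert out.assignments == ("unassigned",)
        assert out.fractions == {}

    def test_overlapping_windows_raise_ambiguity(self):
        # the nu2 windows 1585+-4 and 1591+-4 overlap at 1587-1589
        r = _manual_result([LorentzianComponent(1588.0, 10.0, 1.0)])
        with pytest.raises(AmbiguousAssignmentError, match="1588"):
            assign_species(r, default_assignment_table())


def _manual_result(components):
    from hemecat.raman import DeconvolutionResult

    return DeconvolutionResult(
        components=tuple(components), baseline=(0.0, 0.0), residual_rms=0.0
    )


def _assigned_fixture():
    _, r = _fit_fixture(seed=4)
    out = assign_species(r, default_assignment_table())
    return out, out.assignments


class TestDefaultTable:
    def test_contains_ferryl_nu2_entry(self):
        table = default_assignment_table()
        hits = table.matches(1591.0)
        assert any(e.klass == "FeIV=O" and e.band == "nu2" for e in hits)

    def test_contains_oxidized_nu4_entry(self):
        table = default_assignment_table()
        hits = table.matches(1375.0)
        assert any(e.klass == "HS-FeIII" and e.band == "nu4" for e in hits)

    def test_near_degenerate_nu3_windows_are_disjoint(self):
        table = default_assignment_table()
        pairs = table.overlapping_pairs()
        centers = {(a.center, b.center) for a, b in pairs}
        assert (1504.0, 1508.0) not in centers
        # the +-4 nu2 windows do overlap and are callers' responsibility
        assert (1585.0, 1591.0) in centers

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError, match="unknown observable class"):
            BandAssignment("nu3", 1500.0, (1496, 1504), "odd species", "FeV")


class TestRecoveryProperty:
    def test_randomized_mixtures_recovered(self):
        """Randomized K<=4 mixtures, centers >= 8 cm^-1 apart, SNR >= 50:
        centers within 1 cm^-1 and areas within 10% in >= 95% of replicates."""
        rng = np.random.default_rng(42)
        passed = 0
        n_rep = 20
        for _ in range(n_rep):
            k = int(rng.integers(1, 5))
            while True:
                centers = np.sort(rng.uniform(1440, 1540, size=k))
                if k == 1 or np.diff(centers).min() >= 8.0:
                    break
            truth = [
                LorentzianComponent(float(c), float(rng.uniform(6, 10)), float(rng.uniform(0.5, 1.0)))
                for c in centers
            ]
            s = simulate_spectrum(
                truth, GeneratorSpec(seed=int(rng.integers(2**31)), noise_fraction=0.02)
            )
            r = fit_mixture(s, (1420, 1560), [c.center for c in truth], center_halfwidth=3.0)
            ok = all(
                abs(f.center - t.center) < 1.0 and abs(f.area / t.area - 1.0) < 0.10
                for f, t in zip(r.components, truth)
            )
            passed += ok
        assert passed / n_rep >= 0.95
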