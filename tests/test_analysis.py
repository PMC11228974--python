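import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal, stats

from ciukit import analysis as ana, synthetic as syn
from conftest import species_curve


def make_curve(voltages, ccs, species="s", replicate=0, reference=30.0):
    return ana.UnfoldingCurve(
        species=species, replicate=replicate, voltages=np.asarray(voltages),
        ccs=np.asarray(ccs), reference_voltage=reference,
    )


def logistic_curve(L=33.8, U=37.3, v50=40.3, h=0.8, voltages=None):
    v = np.asarray(voltages if voltages is not None else np.arange(30.0, 61.0))
    return make_curve(v, L + (U - L) / (1 + np.exp(-h * (v - v50))))


class TestCentroid:
    def test_delta_distribution(self):
        d = ana.CCSDistribution(40.0, np.array([33.0, 33.8, 34.0]), np.array([0, 5.0, 0]))
        assert ana.centroid_ccs(d) == pytest.approx(33.8)

    def test_symmetric_pair(self):
        d = ana.CCSDistribution(40.0, np.array([30.0, 40.0]), np.array([1.0, 1.0]))
        assert ana.centroid_ccs(d) == pytest.approx(35.0)

    def test_all_zero_errors(self):
        d = ana.CCSDistribution(40.0, np.array([30.0, 40.0]), np.array([0.0, 0.0]))
        with pytest.raises(ana.AnalysisError):
            ana.centroid_ccs(d)

    def test_bimodal_midpoint(self, instrument):
        # noise-free generator at the midpoint voltage: centroid = mean of states
        sp = syn.SpeciesParams("apo", 33.8, 37.3, 40.0, 0.8)  # v50 on the grid
        curve = species_curve(sp, instrument)
        at_v50 = np.isclose(curve.voltages, sp.v50_unfold)
        expected = 0.5 * (sp.ccs_compact + sp.ccs_extended)
        assert curve.ccs[at_v50][0] == pytest.approx(expected, rel=1e-3)


class TestFingerprint:
    def _dists(self, voltages):
        bins = np.linspace(30, 40, 101)
        out = []
        for i, v in enumerate(voltages):
            inten = np.exp(-0.5 * ((bins - (33 + 0.2 * i)) / 0.5) ** 2) * (i + 1)
            out.append(ana.CCSDistribution(v, bins, inten))
        return out

    def test_column_max_normalized(self):
        fp = ana.build_fingerprint(self._dists([30, 40, 50]))
        assert np.allclose(fp.matrix.max(axis=1), 1.0)

    def test_order_independent(self):
        a = ana.build_fingerprint(self._dists([30, 40, 50]))
        dists = self._dists([30, 40, 50])
        b = ana.build_fingerprint([dists[2], dists[0], dists[1]])
        assert np.array_equal(a.voltages, b.voltages)
        assert np.allclose(a.matrix, b.matrix)

    def test_duplicate_voltages_error(self):
        with pytest.raises(ana.AnalysisError):
            ana.build_fingerprint(self._dists([30, 30, 50]))

    def test_two_ridges_on_synthetic(self, apo_species, instrument):
        model = instrument.calibration_model()
        dists = []
        for v in instrument.voltage_grid:
            atd = syn.simulate_atd(apo_species, instrument, float(v), seed=0)
            dists.append(
                ana.atd_to_ccs_distribution(
                    atd, model, apo_species.mz, apo_species.charge, apo_species.mass
                )
            )
        fp = ana.build_fingerprint(dists)
        ridge_positions = set()
        for row in fp.matrix:
            peaks, _ = signal.find_peaks(row, height=0.5)
            for p in peaks:
                ridge_positions.add(round(fp.ccs_bins[p], 0))
        # exactly two conformer families: compact near 34, extended near 37
        assert len(ridge_positions) <= 3  # adjacent-bin rounding tolerance
        assert any(abs(r - apo_species.ccs_compact) < 1 for r in ridge_positions)
        assert any(abs(r - apo_species.ccs_extended) < 1 for r in ridge_positions)


class TestDeltaCCS:
    def test_zero_at_reference(self):
        curve = logistic_curve()
        d = ana.delta_ccs(curve)
        assert d.ccs[np.isclose(d.voltages, 30.0)][0] == 0.0

    def test_constant_curve_all_zero(self):
        curve = make_curve(np.arange(30.0, 40.0), np.full(10, 33.8))
        assert np.allclose(ana.delta_ccs(curve).ccs, 0.0)

    def test_missing_reference_errors(self):
        curve = make_curve(np.arange(35.0, 45.0), np.arange(10.0), reference=30.0)
        with pytest.raises(ana.AnalysisError):
            ana.delta_ccs(curve)

    def test_plateau_equals_state_separation(self, apo_species, instrument):
        curve = species_curve(apo_species, instrument)
        d = ana.delta_ccs(curve)
        plateau = d.ccs[curve.voltages >= 58].mean()
        truth = apo_species.ccs_extended - apo_species.ccs_compact
        assert plateau == pytest.approx(truth, rel=0.02)


class TestFourPL:
    def test_noise_free_recovery(self):
        curve = logistic_curve(L=33.8, U=37.3, v50=40.3, h=0.8)
        fit = ana.fit_4pl(curve)
        assert fit.converged
        assert fit.lower == pytest.approx(33.8, rel=1e-3)
        assert fit.upper == pytest.approx(37.3, rel=1e-3)
        assert fit.v50 == pytest.approx(40.3, rel=1e-3)
        assert fit.hill == pytest.approx(0.8, rel=1e-3)

    def test_constant_curve_flagged(self):
        curve = make_curve(np.arange(30.0, 40.0), np.full(10, 33.8))
        fit = ana.fit_4pl(curve)
        assert not fit.converged

    def test_voltage_shift_equivariance(self):
        base = logistic_curve()
        shifted = make_curve(base.voltages + 5.0, base.ccs)
        f0, f5 = ana.fit_4pl(base), ana.fit_4pl(shifted)
        assert f5.v50 - f0.v50 == pytest.approx(5.0, abs=1e-6)
        assert f5.hill == pytest.approx(f0.hill, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ana.AnalysisError):
            ana.fit_4pl(make_curve([30, 40, 50], [33, 35, 37]))

    def test_non_convergence_flagged_not_raised(self):
        rng = np.random.default_rng(0)
        curve = make_curve(np.arange(30.0, 40.0), rng.normal(35, 5, 10))
        fit = ana.fit_4pl(curve)  # must not raise
        assert isinstance(fit.converged, bool)


class TestCiuChi:
    def test_chi_50_is_midpoint(self):
        fit = ana.fit_4pl(logistic_curve(v50=40.3))
        assert ana.ciu_chi(fit, 50.0) == fit.v50

    def test_closed_form(self):
        fit = ana.FourPLFit(lower=35.6, upper=39.1, v50=43.8, hill=1.0, rss=0.0,
                            converged=True)
        # 43.8 - ln(9)
        assert ana.ciu_chi(fit, 10.0) == pytest.approx(41.602775422663775, rel=1e-12)

    def test_monotone_in_chi(self):
        fit = ana.fit_4pl(logistic_curve())
        values = [ana.ciu_chi(fit, c) for c in range(10, 100, 10)]
        assert np.all(np.diff(values) > 0)

    def test_chi_out_of_range(self):
        fit = ana.fit_4pl(logistic_curve())
        for chi in (0, 100, -5, 120):
            with pytest.raises(ana.AnalysisError):
                ana.ciu_chi(fit, chi)

    @given(chi=st.floats(1.0, 99.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_of_logistic(self, chi):
        fit = ana.FourPLFit(lower=33.8, upper=37.3, v50=40.3, hill=0.8, rss=0.0,
                            converged=True)
        v = ana.ciu_chi(fit, chi)
        fraction = (fit.predict(v) - fit.lower) / (fit.upper - fit.lower)
        assert fraction == pytest.approx(chi / 100.0, abs=1e-12)


class TestChiProfile:
    def _fits(self, v50s):
        return [
            ana.FourPLFit(lower=33.8, upper=37.3, v50=v, hill=0.8, rss=0.0,
                          converged=True)
            for v in v50s
        ]

    def test_identical_replicates_zero_sd(self):
        profile = ana.chi_profile(self._fits([40.3] * 5))
        assert np.allclose(profile.sd_v, 0.0)

    def test_grid_count(self):
        profile = ana.chi_profile(self._fits([40.0, 41.0]))
        assert profile.chi_grid.size == 9

    def test_nonconverged_excluded_with_warning(self):
        fits = self._fits([40.0, 41.0, 42.0])
        fits[1] = ana.FourPLFit(lower=0, upper=0, v50=float("nan"), hill=float("nan"),
                                rss=0.0, converged=False)
        with pytest.warns(UserWarning):
            profile = ana.chi_profile(fits)
        assert profile.n_replicates == 2

    def test_all_excluded_errors(self):
        bad = ana.FourPLFit(lower=0, upper=0, v50=float("nan"), hill=float("nan"),
                            rss=0.0, converged=False)
        with pytest.warns(UserWarning), pytest.raises(ana.AnalysisError):
            ana.chi_profile([bad, bad])


class TestAnova:
    def test_hand_computed_f(self):
        result = ana.anova_compare({"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]})
        assert result.f_stat == pytest.approx(3.0, rel=1e-12)

    def test_null_case(self):
        result = ana.anova_compare({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        assert result.f_stat == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_all_identical(self):
        result = ana.anova_compare({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert result.degenerate
        assert result.p_value == 1.0

    def test_two_groups_equals_t_squared(self):
        a, b = [40.1, 40.5, 39.9, 40.3], [43.0, 43.4, 42.8, 43.1]
        result = ana.anova_compare({"a": a, "b": b})
        t, _ = stats.ttest_ind(a, b)
        assert result.f_stat == pytest.approx(t**2, rel=1e-9)

    def test_requires_two_groups_of_two(self):
        with pytest.raises(ana.AnalysisError):
            ana.anova_compare({"a": [1, 2]})
        with pytest.raises(ana.AnalysisError):
            ana.anova_compare({"a": [1, 2], "b": [3]})


class TestEjection:
    def test_fraction_half(self):
        assert ana.ejection_fraction(100.0, 100.0) == pytest.approx(0.5)

    def test_fraction_zero(self):
        assert ana.ejection_fraction(100.0, 0.0) == 0.0

    def test_both_zero_errors(self):
        with pytest.raises(ana.AnalysisError):
            ana.ejection_fraction(0.0, 0.0)

    def test_round_trip_v50(self):
        v = np.arange(30.0, 55.0, 0.5)
        frac = 1 - syn.survival_fraction(v, 42.0, 1.5)
        curve = ana.fit_ejection(v, frac)
        assert curve.converged
        assert curve.v50_eject == pytest.approx(42.0, abs=0.1)
        assert curve.slope_eject == pytest.approx(1.5, rel=1e-3)

    def test_constant_zero_degenerate(self):
        curve = ana.fit_ejection(np.arange(30.0, 40.0), np.zeros(10))
        assert not curve.converged

    def test_monotone_data_positive_slope(self):
        v = np.arange(35.0, 50.0)
        curve = ana.fit_ejection(v, np.linspace(0.05, 0.95, v.size))
        assert curve.slope_eject > 0

    def test_too_few_points(self):
        with pytest.raises(ana.AnalysisError):
            ana.fit_ejection(np.array([40.0, 41, 42]), np.array([0.2, 0.5, 0.8]))


class TestElab:
    def test_paper_range(self):
        assert ana.elab(30, 12) == 360.0
        assert ana.elab(60, 12) == 720.0

    def test_mid_value(self):
        assert ana.elab(40, 12) == 480.0

    def test_invalid_charge(self):
        with pytest.raises(ana.AnalysisError):
            ana.elab(40, 0)


@pytest.fixture(scope="module")
def profiles():
    inst = syn.InstrumentParams(n_replicates=1)
    binary = syn.SpeciesParams("binary", 34.7, 38.2, 43.2, 0.8)
    ternary = syn.SpeciesParams(
        "ternary", 35.6, 39.1, 43.2, 0.8,
        ejection=syn.EjectionParams(42.0, 1.0, coupling=2.5),
    )
    apo = syn.SpeciesParams("apo", 33.8, 37.3, 40.3, 0.8)
    return {sp.name: ana.fit_4pl(species_curve(sp, inst)) for sp in (apo, binary, ternary)}


class TestOrderingAndMasking:
    """Noise-free ordering/masking behavior of the full synthetic pipeline."""

    def test_ordering_preserved(self, profiles):
        for chi in range(10, 100, 10):
            assert ana.ciu_chi(profiles["apo"], chi) < ana.ciu_chi(
                profiles["binary"], chi
            )

    def test_masking_low_chi_separation_larger(self, profiles):
        sep10 = ana.ciu_chi(profiles["ternary"], 10) - ana.ciu_chi(profiles["binary"], 10)
        sep50 = ana.ciu_chi(profiles["ternary"], 50) - ana.ciu_chi(profiles["binary"], 50)
        assert sep10 > sep50 > 0
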