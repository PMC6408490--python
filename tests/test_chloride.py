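"""Saturation-enhancement model: algebra, per-solvent and global fits,
and the baseline-rate-versus-binding-constant linear relation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chlorokinetics as ck


class TestSaturationFraction:
    @pytest.mark.parametrize(
        "kcl,cl,expected", [(2.0, 0.0, 0.0), (1.0, 1.0, 0.5), (4.0, 1.0, 0.8)]
    )
    def test_values(self, kcl, cl, expected):
        assert ck.saturation_fraction(kcl, cl) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ck.ValidationError):
            ck.saturation_fraction(-1.0, 0.5)
        with pytest.raises(ck.ValidationError):
            ck.saturation_fraction(1.0, -0.5)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(kcl=st.floats(0, 1e4), cl=st.floats(0, 1e3))
    def test_bounded_in_unit_interval(self, kcl, cl):
        f = ck.saturation_fraction(kcl, cl)
        assert 0.0 <= f <= 1.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        kcl=st.floats(0.01, 100), cl=st.floats(0.01, 10), bump=st.floats(0.01, 10)
    )
    def test_monotone_in_both_arguments(self, kcl, cl, bump):
        f = ck.saturation_fraction(kcl, cl)
        assert ck.saturation_fraction(kcl + bump, cl) >= f
        assert ck.saturation_fraction(kcl, cl + bump) >= f

    def test_speciation_record(self):
        sp = ck.TransitionStateSpeciation.at(4.0, 1.0)
        assert sp.fraction_bound == pytest.approx(0.8)


class TestEnhancedRate:
    def test_baseline_and_plateau_limits(self):
        assert ck.enhanced_rate(10.0, 5.0, 2.0, 0.0) == 10.0
        assert ck.enhanced_rate(10.0, 5.0, 2.0, 1e9) == pytest.approx(60.0, rel=1e-6)

    def test_half_saturation_value(self):
        assert ck.enhanced_rate(10.0, 5.0, 2.0, 0.5) == pytest.approx(35.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        r_o=st.floats(0.1, 100),
        r_e=st.floats(0.1, 20),
        kcl=st.floats(0.1, 50),
    )
    def test_concave_increasing_in_chloride(self, r_o, r_e, kcl):
        cl = np.linspace(0, 3, 40)
        k = ck.enhanced_rate(r_o, r_e, kcl, cl)
        assert np.all(np.diff(k) > 0)
        assert np.all(np.diff(k, 2) <= 1e-12 * r_o)


class TestSingleSolventFit:
    def test_noiseless_inversion_recovers_parameters(self):
        d = ck.ChlorideDesign(
            [0.9], [10.0], [2.0], 5.0, [0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.5]
        )
        tab = ck.generate_chloride_table(d, noise_cv=0.0)
        fit = ck.fit_single_solvent(tab[["cl_M", "k_obs"]])
        sf = next(iter(fit.per_solvent.values()))
        assert sf.r_o == pytest.approx(10.0, rel=1e-6)
        assert sf.K_Cl == pytest.approx(2.0, rel=1e-6)
        assert fit.r_enhance == pytest.approx(5.0, rel=1e-6)
        assert sf.kcl_identifiable

    def test_flat_table_flags_unidentifiable_binding_constant(self):
        cl = np.array([0.0, 0.1, 0.5, 1.0, 2.0])
        k = np.full_like(cl, 10.0)
        fit = ck.fit_single_solvent((cl, k))
        sf = next(iter(fit.per_solvent.values()))
        assert fit.r_enhance == pytest.approx(0.0, abs=1e-3)
        assert not sf.kcl_identifiable
        assert sf.K_Cl_ci95[1] == math.inf

    def test_noisy_recovery_of_binding_constant(self):
        d = ck.ChlorideDesign(
            [0.9], [10.0], [2.0], 5.0,
            [0.0, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0, 1.5, 2.5],
        )
        errs = []
        for seed in range(100):
            tab = ck.generate_chloride_table(d, noise_cv=0.05, seed=seed)
            fit = ck.fit_single_solvent(tab[["cl_M", "k_obs"]])
            sf = next(iter(fit.per_solvent.values()))
            errs.append(abs(sf.K_Cl - 2.0) / 2.0)
        assert np.median(errs) < 0.15

    def test_too_few_levels_rejected(self):
        with pytest.raises(ck.ValidationError):
            ck.fit_single_solvent((np.array([0, 0.5, 1.0]), np.array([1, 2, 3.0])))


class TestGlobalFit:
    def test_noiseless_five_solvent_design_exact(self):
        tab = ck.generate_chloride_table(ck.reference_chloride_design(), noise_cv=0.0)
        fit = ck.fit_global(tab)
        assert fit.r_enhance == pytest.approx(5.0, rel=1e-6)
        design = ck.reference_chloride_design()
        for frac, ko, kcl in zip(
            design.solvent_fractions, design.k_o, design.K_Cl
        ):
            sf = fit.per_solvent[frac]
            assert sf.r_o == pytest.approx(ko, rel=1e-6)
            assert sf.K_Cl == pytest.approx(kcl, rel=1e-6)
            assert sf.r_squared > 0.999999

    def test_shared_fit_sse_exceeds_free_fit_sse_when_enhancements_differ(self):
        # two solvents generated with different enhancement factors
        d1 = ck.ChlorideDesign([0.25], [2.0], [3.0], 3.0,
                               [0.0, 0.05, 0.1, 0.5, 1.0, 2.0])
        d2 = ck.ChlorideDesign([0.9], [20.0], [25.0], 8.0,
                               [0.0, 0.05, 0.1, 0.5, 1.0, 2.0])
        import pandas as pd
        tab = pd.concat([
            ck.generate_chloride_table(d1, 0.0),
            ck.generate_chloride_table(d2, 0.0),
        ])
        shared = ck.fit_global(tab, shared=True)
        free = ck.fit_global(tab, shared=False)
        assert shared.sse > free.sse
        ftest = ck.shared_enhancement_ftest(tab)
        assert ftest["sse_shared"] > ftest["sse_free"]

    def test_single_solvent_delegates(self):
        d = ck.ChlorideDesign([0.9], [10.0], [2.0], 5.0,
                              [0.0, 0.05, 0.1, 0.5, 1.0, 2.5])
        tab = ck.generate_chloride_table(d, noise_cv=0.0)
        fit = ck.fit_global(tab)
        assert list(fit.per_solvent) == [0.9]
        assert fit.r_enhance == pytest.approx(5.0, rel=1e-6)

    def test_enhancement_invariant_to_rescaling_rates(self):
        tab = ck.generate_chloride_table(
            ck.reference_chloride_design(), noise_cv=0.05, seed=5
        )
        scaled = tab.assign(k_obs=tab.k_obs * 37.0)
        a = ck.fit_global(tab)
        b = ck.fit_global(scaled)
        assert a.r_enhance == pytest.approx(b.r_enhance, rel=1e-6)

    def test_noisy_recovery_within_ten_percent(self):
        tab = ck.generate_chloride_table(
            ck.reference_chloride_design(), noise_cv=0.05, seed=42
        )
        fit = ck.fit_global(tab)
        assert fit.r_enhance == pytest.approx(5.0, rel=0.10)


class TestLinearRelation:
    def test_exact_line_recovered(self):
        kcl = {f: v for f, v in zip([0.05, 0.25, 0.5, 0.75, 0.9],
                                    [1.5, 3.0, 7.0, 14.0, 25.0])}
        k_free = {f: 0.84 * v - 0.87 for f, v in kcl.items()}
        rel = ck.k_vs_Kcl_relation(kcl, k_free)
        assert rel.slope == pytest.approx(0.84)
        assert rel.intercept == pytest.approx(-0.87)
        assert rel.r_squared == pytest.approx(1.0)

    def test_degenerate_constant_response(self):
        kcl = {"a": 1.0, "b": 2.0, "c": 3.0}
        k_free = {"a": 5.0, "b": 5.0, "c": 5.0}
        rel = ck.k_vs_Kcl_relation(kcl, k_free)
        assert rel.slope == 0.0 and rel.r_squared == 0.0

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ck.ValidationError):
            ck.k_vs_Kcl_relation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_slope_ci_coverage_on_noisy_lines(self):
        rng_covered = 0
        n_rep = 200
        x = np.array([1.5, 3.0, 7.0, 14.0, 25.0])
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            y = 0.84 * x - 0.87 + rng.normal(0, 0.5, x.size)
            rel = ck.k_vs_Kcl_relation(
                dict(zip("abcde", x)), dict(zip("abcde", y))
            )
            lo, hi = rel.slope_ci95
            rng_covered += lo <= 0.84 <= hi
        assert rng_covered / n_rep >= 0.90
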