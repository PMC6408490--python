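"""Generator correctness: closed-form kinetics, mass balance, noise
reproducibility, and the saturation law used for chloride tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chlorokinetics as ck
from chlorokinetics.synthetic import batch_concentrations


class TestSimulateProfile:
    def test_half_life_of_noiseless_decay(self, make_profile, gvl_hcl_condition):
        # k=62 M^-1 ks^-1 at [H+]=5 mM gives t_half = ln2/0.31 = 2.236 ks
        cond = gvl_hcl_condition
        spec = ck.GeneratorSpec(
            conditions=[cond], true_k={cond: 62.0}, noise_cv=0.0,
            sample_times=[2.2359773], seed=0,
        )
        p = ck.simulate_profile(spec, cond, r0=0.050)
        assert p.reactant[0] / 0.050 == pytest.approx(0.5, rel=1e-4)

    def test_zero_rate_constant_is_inert(self, gvl_hcl_condition):
        cond = gvl_hcl_condition
        spec = ck.GeneratorSpec(
            conditions=[cond], true_k={cond: 0.0}, noise_cv=0.0,
            sample_times=np.linspace(0, 10, 6), seed=0,
        )
        p = ck.simulate_profile(spec, cond)
        assert np.allclose(p.reactant, p.reactant[0])
        assert np.all(p.primary == 0) and np.all(p.secondary == 0)

    def test_mass_balance_with_full_selectivity_no_degradation(self, make_profile):
        p = make_profile(k=62.0, selectivity=1.0, k_deg=0.0, noise_cv=0.0)
        np.testing.assert_allclose(p.reactant + p.primary, p.reactant[0], rtol=1e-12)

    @pytest.mark.parametrize("selectivity,k_deg", [(0.78, 1.0), (0.5, 62.0), (1.0, 5.0)])
    def test_mass_conservation_with_humin_branch(self, selectivity, k_deg):
        # R + P + S + humins == R0 at every time; humins = (1-s)*(R0-R) >= 0
        t = np.linspace(0, 10, 50)
        c = batch_concentrations(t, 0.05, 0.31, selectivity, k_deg * 0.005)
        humins = (1 - selectivity) * (0.05 - c[ck.REACTANT])
        total = c[ck.REACTANT] + c[ck.PRIMARY] + c[ck.SECONDARY] + humins
        np.testing.assert_allclose(total, 0.05, rtol=1e-10)
        assert np.all(humins >= -1e-15)
        assert np.all(c[ck.SECONDARY] >= 0)

    def test_equal_rate_degenerate_limit_continuous(self):
        t = np.linspace(0, 10, 20)
        near = batch_concentrations(t, 0.05, 0.31, 0.8, 0.31 * (1 + 1e-9))
        exact = batch_concentrations(t, 0.05, 0.31, 0.8, 0.31)
        np.testing.assert_allclose(near[ck.PRIMARY], exact[ck.PRIMARY], rtol=1e-6)

    def test_seed_reproducibility_and_distinct_noise(self, make_profile):
        a = make_profile(noise_cv=0.05, seed=11)
        b = make_profile(noise_cv=0.05, seed=11)
        c = make_profile(noise_cv=0.05, seed=12)
        np.testing.assert_array_equal(a.reactant, b.reactant)
        assert not np.array_equal(a.reactant, c.reactant)

    def test_unknown_condition_raises(self, gvl_hcl_condition):
        cond = gvl_hcl_condition
        spec = ck.GeneratorSpec(
            conditions=[cond], true_k={cond: 1.0}, sample_times=[0, 1], seed=0,
        )
        other = ck.ExperimentCondition(gvl_massfrac=0.5, acid_conc=0.005)
        with pytest.raises(ck.MissingConditionError):
            ck.simulate_profile(spec, other)

    def test_negative_times_rejected(self, gvl_hcl_condition):
        cond = gvl_hcl_condition
        with pytest.raises(ck.ValidationError):
            ck.GeneratorSpec(
                conditions=[cond], true_k={cond: 1.0}, sample_times=[-1, 0, 1],
            )


class TestChlorideTable:
    def test_zero_chloride_returns_baseline(self):
        d = ck.ChlorideDesign([0.9], [10.0], [2.0], 5.0, [0.0, 0.1, 0.5, 1.0])
        tab = ck.generate_chloride_table(d, noise_cv=0.0)
        assert tab.loc[tab.cl_M == 0.0, "k_obs"].item() == pytest.approx(10.0)

    def test_saturation_limit(self):
        d = ck.ChlorideDesign([0.9], [10.0], [1e6], 5.0, [0.0, 1.0, 10.0, 100.0])
        tab = ck.generate_chloride_table(d, noise_cv=0.0)
        assert tab["k_obs"].iloc[-1] == pytest.approx(60.0, rel=1e-4)

    def test_direct_evaluation_at_half_saturation(self):
        # K_Cl*cl = 1 -> f = 0.5 -> k = 10 * (1 + 5*0.5) = 35
        d = ck.ChlorideDesign([0.9], [10.0], [2.0], 5.0, [0.0, 0.1, 0.25, 0.5])
        tab = ck.generate_chloride_table(d, noise_cv=0.0)
        assert tab.loc[tab.cl_M == 0.5, "k_obs"].item() == pytest.approx(35.0)

    def test_noiseless_values_nondecreasing_in_cl(self):
        tab = ck.generate_chloride_table(ck.reference_chloride_design(), noise_cv=0.0)
        for _, grp in tab.groupby("gvl_massfrac"):
            k = grp.sort_values("cl_M")["k_obs"].to_numpy()
            assert np.all(np.diff(k) >= 0)

    def test_deterministic_given_seed(self):
        d = ck.reference_chloride_design()
        a = ck.generate_chloride_table(d, noise_cv=0.05, seed=4)
        b = ck.generate_chloride_table(d, noise_cv=0.05, seed=4)
        assert a.equals(b)

    def test_negative_chloride_rejected(self):
        with pytest.raises(ck.ValidationError):
            ck.ChlorideDesign([0.9], [10.0], [2.0], 5.0, [-0.1, 0.5])


class TestArrheniusSet:
    def test_zero_barrier_gives_constant_rate(self):
        tab = ck.generate_arrhenius_set(0.0, 3.0, [353, 373, 393], noise_cv=0.0)
        assert np.allclose(tab["k"], np.exp(3.0))

    def test_rate_ratio_over_20K_at_110_kJ(self):
        # exp(110/R * (1/373 - 1/393)) ~ 6.08
        tab = ck.generate_arrhenius_set(110.0, 38.0, [373.0, 393.0], noise_cv=0.0)
        ratio = tab["k"].iloc[1] / tab["k"].iloc[0]
        expected = np.exp(110.0 / ck.R_GAS * (1 / 373.0 - 1 / 393.0))
        assert ratio == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(6.08, rel=0.01)

    def test_seeded_regeneration_identical(self):
        a = ck.generate_arrhenius_set(110.0, 38.0, [363, 373, 383], 0.05, seed=2)
        b = ck.generate_arrhenius_set(110.0, 38.0, [363, 373, 383], 0.05, seed=2)
        assert a.equals(b)

    def test_empty_temperature_list_rejected(self):
        with pytest.raises(ck.ValidationError):
            ck.generate_arrhenius_set(110.0, 38.0, [])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    k=st.floats(0.1, 100.0),
    selectivity=st.floats(0.0, 1.0),
    k_deg=st.floats(0.0, 50.0),
)
def test_noiseless_profile_matches_analytic_solution(k, selectivity, k_deg):
    cond = ck.ExperimentCondition(acid_conc=0.005, gvl_massfrac=0.9)
    t = np.linspace(0.0, 3.0 / (k * 0.005), 8)
    spec = ck.GeneratorSpec(
        conditions=[cond], true_k={cond: k}, selectivity=selectivity,
        k_deg=k_deg, noise_cv=0.0, sample_times=t, seed=0,
    )
    p = ck.simulate_profile(spec, cond, r0=0.05)
    expected = batch_concentrations(t, 0.05, k * 0.005, selectivity, k_deg * 0.005)
    for species in ck.SPECIES:
        np.testing.assert_allclose(
            p.concentrations[species], expected[species], rtol=1e-12, atol=1e-18
        )
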