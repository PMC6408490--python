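import numpy as np
import pytest

import chlorokinetics as ck


@pytest.fixture
def gvl_hcl_condition():
    """90% GVL / 10% water with 5 mM HCl at 373 K."""
    return ck.ExperimentCondition(
        solvent="GVL/H2O", gvl_massfrac=0.9, acid_name="HCl", acid_conc=0.005,
        temperature=373.0,
    )


@pytest.fixture
def make_profile(gvl_hcl_condition):
    """Factory for single-condition synthetic profiles with sampling scaled
    to ~3 half-lives of the requested rate constant."""

    def _make(
        k=62.0,
        noise_cv=0.0,
        seed=0,
        selectivity=0.78,
        k_deg=0.0,
        condition=None,
        n_points=10,
        n_halflives=4,
    ):
        cond = condition or gvl_hcl_condition
        t_end = n_halflives * np.log(2.0) / (k * cond.acid_conc) if k > 0 else 12.0
        spec = ck.GeneratorSpec(
            conditions=[cond],
            true_k={cond: k},
            selectivity=selectivity,
            k_deg=k_deg,
            noise_cv=noise_cv,
            sample_times=np.linspace(0.0, t_end, n_points),
            seed=seed,
        )
        return ck.simulate_profile(spec, cond)

    return _make
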