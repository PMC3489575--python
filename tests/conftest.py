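import numpy as np
import pytest

import gmtrial as gm


@pytest.fixture(scope="session")
def default_design() -> gm.TrialDesign:
    return gm.build_design(4, 4, 6)


@pytest.fixture(scope="session")
def default_varcomps() -> gm.VarianceComponents:
    return gm.VarianceComponents(
        sigma2_site=0.04,
        sigma2_block=0.005,
        sigma2_genotype=0.02,
        sigma2_interaction=0.01,
        sigma2_residual=0.01,
    )


@pytest.fixture(scope="session")
def default_config(default_design, default_varcomps) -> gm.SimulationConfig:
    return gm.SimulationConfig(
        design=default_design,
        means=gm.MeanStructure(mu_overall=1.0),
        varcomps=default_varcomps,
        seed=12345,
    )


@pytest.fixture(scope="session")
def simulated_dataset(default_config) -> gm.TrialDataset:
    return gm.simulate_trial(default_config)


def make_decomposition_from_ms(
    design: gm.TrialDesign, ms: dict[str, float]
) -> gm.AnovaDecomposition:
    """Build a decomposition whose mean squares are set exactly to ``ms``.

    Used to feed EMS-consistent inputs to the moment estimator.
    """
    import pandas as pd

    from gmtrial.anova import STRATA, _stratum_dfs

    dfs = _stratum_dfs(design)
    table = pd.DataFrame(
        {
            "ss": [ms[s] * dfs[s] for s in STRATA],
            "df": [dfs[s] for s in STRATA],
        },
        index=list(STRATA),
    )
    table["ms"] = [ms[s] for s in STRATA]
    total_ss = float(table["ss"].sum())
    return gm.AnovaDecomposition(
        table=table, total_ss=total_ss, total_df=design.n_plots - 1, design=design
    )
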