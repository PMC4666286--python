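import numpy as np
import pytest

import wgreg as w


@pytest.fixture(scope="session")
def interaction_fit():
    """A medium interaction-model BRR fit on synthetic two-group data.

    Shared by posthoc/diagnostic tests; truth: var_main=0.3,
    var_int=(0.15, 0.10), sigma2=(0.6, 0.8).
    """
    geno, std, groups, phen, truth = w.simulate_dataset(
        [400, 400], 200, 0.3, [0.15, 0.10], sigma2=[0.6, 0.8],
        differentiation=0.2, seed=101,
    )
    layout = w.build_design(std, groups, "interaction")
    cfg = w.ModelConfig(
        mode="interaction", prior="BRR",
        mcmc=w.MCMCSettings(iterations=6000, burnin=2000, thin=5, seed=202),
    )
    summary = w.fit(phen, layout, cfg)
    return {
        "geno_std": std, "groups": groups, "phenos": phen,
        "truth": truth, "layout": layout, "summary": summary,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
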