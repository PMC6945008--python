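import pytest

from mixsel import IndexWeights, SchemeDesign
from mixsel.experiments import default_designs, make_params


@pytest.fixture(scope="session")
def worked_params():
    """Standard worked-example point: sigma_v^2=1, sigma_a^2=0.5, all
    correlations -0.5, interaction variances 0.25, plot error 2."""
    return make_params(0.5, 0.5, -0.5)


@pytest.fixture(scope="session")
def designs():
    """Equal-budget designs: 900 plots, 3 replicates, 10%/20% rates."""
    return default_designs()


@pytest.fixture(scope="session")
def ones():
    return IndexWeights(alpha_1=1.0, alpha_2=1.0)


@pytest.fixture()
def small_design():
    return SchemeDesign(total_plots=6, replicates=3, selection_rate=0.5)
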