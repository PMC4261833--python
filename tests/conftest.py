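import numpy as np
import pytest

from phenoflux.model import Metabolite, Model, Reaction


@pytest.fixture(scope="session")
def chain_model():
    """EX_A (uptake <= 10) -> A[c] -> biomass: optimum 10."""
    m = Model(id="chain")
    m.add_metabolite(Metabolite("A[c]"))
    m.add_reaction(
        Reaction(
            id="EX_A",
            stoichiometry={"A[c]": -1},
            reversible=True,
            lower_bound=-10.0,
            upper_bound=0.0,
            category="exchange",
        )
    )
    m.add_reaction(Reaction(id="biomass", stoichiometry={"A[c]": -1}))
    m.objective = "biomass"
    return m


@pytest.fixture()
def parallel_model():
    """Two routes with caps 3 and 4 feeding biomass: optimum 7."""
    m = Model(id="parallel")
    for mid in ("S[c]", "P[c]"):
        m.add_metabolite(Metabolite(mid))
    m.add_reaction(
        Reaction(
            id="EX_S", stoichiometry={"S[c]": -1}, reversible=True,
            lower_bound=-1000.0, upper_bound=0.0, category="exchange",
        )
    )
    m.add_reaction(
        Reaction(id="route1", stoichiometry={"S[c]": -1, "P[c]": 1},
                 upper_bound=3.0)
    )
    m.add_reaction(
        Reaction(id="route2", stoichiometry={"S[c]": -1, "P[c]": 1},
                 upper_bound=4.0)
    )
    m.add_reaction(Reaction(id="biomass", stoichiometry={"P[c]": -1}))
    m.objective = "biomass"
    return m


@pytest.fixture(scope="session")
def base_model():
    from phenoflux.synth import synthetic_base_model

    return synthetic_base_model()


@pytest.fixture(scope="session")
def manifest():
    from phenoflux.model import study_manifest

    return study_manifest()


@pytest.fixture(scope="session")
def expanded(base_model, manifest):
    from phenoflux.model import expand_model

    return expand_model(base_model, manifest)


def logistic_series(amplitude, steepness, midpoint, t_max=168.0, dt=0.25,
                    baseline=0.0):
    t = np.arange(0.0, t_max + dt / 2, dt)
    return t, baseline + amplitude / (1.0 + np.exp(-steepness * (t - midpoint)))


def logistic_lag(steepness, midpoint):
    """Exact tangent-intercept lag of a logistic observed from t=0.

    The tangent at the midpoint (slope A*k/4, height A/2) is intersected
    with the curve's value at t=0, A/(1+e^{k*mid}), which is not exactly
    zero for finite k*mid:  lag = mid - (2/k) * (1 - 2/(1+e^{k*mid})).
    """
    return midpoint - (2.0 / steepness) * (
        1.0 - 2.0 / (1.0 + np.exp(steepness * midpoint))
    )
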