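import pytest

from lognnc import gauss_hermite_rule, leipzig_like, make_route, simulate_campaign
from lognnc.design import Categorical, Intercept, Linear, ModelSpec


@pytest.fixture(scope="session")
def rule64():
    return gauss_hermite_rule(64)


@pytest.fixture(scope="session")
def rule24():
    return gauss_hermite_rule(24)


@pytest.fixture(scope="session")
def small_campaign():
    """A compact Leipzig-like campaign with fixed-effect-only truth."""
    tpl = leipzig_like(seed=314, n_days=8, steps_per_segment=2,
                       hour_amp_mu=0.0, traffic_amp_mu=0.0, noise_logrw_sd=0.0,
                       space_sd_mu=0.0, space_sd_sigma=0.0,
                       time_sd_mu=0.0, time_sd_sigma=0.0)
    route = make_route(tpl)
    records, truth = simulate_campaign(tpl, route)
    return tpl, route, records, truth


@pytest.fixture(scope="session")
def basic_spec():
    terms = lambda: [  # noqa: E731
        Intercept(), Linear("ws"),
        Categorical("strclass", "park",
                    ("park", "residential", "tertiary", "secondary", "primary")),
        Categorical("strconf", "open", ("open", "half-open", "canyon")),
        Categorical("weekday", "weekend", ("weekend", "weekday")),
        Categorical("season", "summer", ("summer", "winter")),
    ]
    return ModelSpec(mu=terms(), sigma=terms(), lam=[Intercept()])
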