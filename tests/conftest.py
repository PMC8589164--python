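import numpy as np
import pytest

import apixvka as av


@pytest.fixture(scope="session")
def config():
    """The shipped parameter pack with the synthetic life table."""
    return av.load_parameter_pack()


@pytest.fixture(scope="session")
def space():
    return av.enumerate_states()


@pytest.fixture(scope="session")
def base_case(config):
    return av.run_base_case(config)


def make_degenerate_config(config, *, zero_rates=True, zero_mortality=True,
                           zero_discontinuation=True, utility_one=False,
                           zero_discount=False, event_free_start=False):
    """Strip selected dynamics from a config for closed-form checks."""
    cfg = config.copy()
    if zero_rates:
        for key in list(cfg.rates.rates):
            for e in av.EVENTS:
                cfg.rates.rates[key][e] = 0.0
    if zero_mortality:
        qx = np.zeros(len(cfg.life_table.qx))
        qx[cfg.life_table.ages >= cfg.terminal_age] = 1.0
        cfg.life_table.qx = qx
    if zero_discontinuation:
        for e in cfg.discontinuation.per_event:
            cfg.discontinuation.per_event[e] = 0.0
        for arm in cfg.discontinuation.per_cycle_unrelated:
            cfg.discontinuation.per_cycle_unrelated[arm] = 0.0
    if utility_one:
        cfg.utilities.baseline_coeffs = {"intercept": 1.0, "male": 0.0,
                                         "age": 0.0, "age2": 0.0}
        for e in cfg.utilities.acute_ratio:
            cfg.utilities.acute_ratio[e] = 1.0
        for e in cfg.utilities.post_ratio:
            cfg.utilities.post_ratio[e] = 1.0
    if zero_discount:
        cfg.discount_rate_annual = 0.0
    if event_free_start:
        cfg.cohort.initial_postacute_mi_share = 0.0
    return cfg


@pytest.fixture()
def degenerate_config(config):
    return make_degenerate_config(config)
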