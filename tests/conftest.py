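import numpy as np
import pytest

from psychfield import load_instrument
from psychfield.instrument import InstrumentSpec, SubscaleSpec
from psychfield.simulate import SimulationConfig, simulate, uniform_factor_corr


@pytest.fixture(scope="session")
def spec():
    return load_instrument("pedsql_nf1_adult")


def make_instrument(sizes, name="toy", exclusions=(), sensitive_last=False):
    """Build a generic instrument with the given subscale sizes."""
    subs = []
    for s_idx, k in enumerate(sizes):
        sens = sensitive_last and s_idx == len(sizes) - 1
        subs.append(
            SubscaleSpec(
                name=f"Scale{s_idx + 1}",
                items=tuple((f"s{s_idx + 1}i{j + 1}", f"item {j + 1}") for j in range(k)),
                sensitive=sens,
            )
        )
    return InstrumentSpec(
        name=name, subscales=tuple(subs), total_score_exclusions=frozenset(exclusions)
    )


@pytest.fixture(scope="session")
def sim134(spec):
    """Default reference scenario: 134 respondents, seed 1."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def ds134(sim134):
    return sim134[0]


@pytest.fixture(scope="session")
def ds600_shift(spec):
    """n=600 with the default ordered +-0.8 SD health-group shifts."""
    ds, _ = simulate(SimulationConfig(n_respondents=600, seed=11))
    return ds


@pytest.fixture(scope="session")
def ds600_null(spec):
    """n=600 with zero group shifts (null known-groups model)."""
    ds, _ = simulate(
        SimulationConfig(n_respondents=600, group_shifts=(0.0, 0.0, 0.0), seed=12)
    )
    return ds


@pytest.fixture(scope="session")
def ds2000_block(spec):
    """n=2000, uncorrelated factors, high loadings, no missingness."""
    n_sub = len(spec.subscales)
    cfg = SimulationConfig(
        n_respondents=2000,
        factor_corr=np.eye(n_sub),
        loadings=0.9,
        item_missing_rate=0.0,
        sensitive_block_missing_rate=0.0,
        seed=13,
    )
    ds, _ = simulate(cfg)
    return ds


def single_scale_dataset(k_items, lam, n, seed, rho=0.0):
    """Simulate one k-item subscale plus a 2-item dummy subscale.

    Returns (dataset, instrument); the subscale of interest is Scale1.
    """
    inst = make_instrument([k_items, 2])
    cfg = SimulationConfig(
        n_respondents=n,
        instrument=inst,
        factor_corr=uniform_factor_corr(2, rho),
        loadings=lam,
        item_missing_rate=0.0,
        sensitive_block_missing_rate=0.0,
        group_shifts=(0.0, 0.0, 0.0),
        seed=seed,
    )
    ds, _ = simulate(cfg)
    return ds, inst
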