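import dataclasses

import numpy as np
import pandas as pd
import pytest

import pulsekin as pk


@pytest.fixture
def default_params():
    return pk.SwimmerParams()


@pytest.fixture
def noiseless_traj(default_params):
    p = default_params
    return pk.simulate_swimmer(p, duration=4.0, dt=0.004, seed=0)


@pytest.fixture
def study_tree():
    return pk.load_default_tree()


@pytest.fixture
def four_tip_tree():
    return pk.parse_newick("((A:1,B:1):0.5,(C:0.8,D:1.2):0.7);")


def deep_balanced_newick(n_levels: int = 4, tip_bl: float = 0.05,
                         internal_bl: float = 1.0) -> str:
    """Balanced 2^n-tip tree with short terminal and long internal branches."""
    names = iter(f"T{i:02d}" for i in range(2**n_levels))

    def clade(d: int) -> str:
        if d == 1:
            return f"({next(names)}:{tip_bl},{next(names)}:{tip_bl}):{internal_bl}"
        return f"({clade(d - 1)},{clade(d - 1)}):{internal_bl}"

    return f"({clade(n_levels - 1)},{clade(n_levels - 1)});"


@pytest.fixture
def deep_balanced_tree():
    return pk.parse_newick(deep_balanced_newick())


def noisy_variant(params: pk.SwimmerParams, frac: float = 0.02) -> pk.SwimmerParams:
    """noise_sd set to `frac` of the analytic per-cycle displacement."""
    per_cycle = pk.analytic_metrics(params)["P_dist"]
    return dataclasses.replace(params, noise_sd=frac * per_cycle)


def random_params(rng: np.random.Generator) -> pk.SwimmerParams:
    fc = rng.uniform(0.2, 0.4)
    fi = rng.uniform(0.1, 0.3)
    peak = rng.uniform(2.0, 5.0)
    return pk.SwimmerParams(
        pulse_freq=rng.uniform(1.0, 4.0),
        frac_contraction=fc,
        frac_relaxation=1.0 - fc - fi,
        frac_interpulse=fi,
        peak_velocity=peak,
        trough_velocity=rng.uniform(0.0, 0.3) * peak,
        interpulse_gain=rng.uniform(0.0, 0.3),
        bell_diameter_relaxed=rng.uniform(0.5, 6.0),
        heading=rng.uniform(0, 2 * np.pi),
    )
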