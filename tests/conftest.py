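import numpy as np
import pandas as pd
import pytest

from clonotrace import SimulationConfig, simulate_cohort


def make_obs(rows):
    """Observation table from (patient, variant, gene, day, comp, alt, depth)."""
    from clonotrace.io import _validate_observations

    df = pd.DataFrame(rows, columns=["patient_id", "variant_id", "gene",
                                     "day", "compartment", "alt", "depth"])
    return _validate_observations(df, "fixture")


def make_sc_matrix(patterns, lineages=None, car=None, amplicons=("A", "B", "C")):
    """Single-cell matrix from per-cell mutant amplicon sets (None = NA cell)."""
    n = len(patterns)
    lineages = lineages or ["monocyte"] * n
    car = car if car is not None else [False] * n
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "clone_truth": ["?"] * n,
        "lineage": lineages,
        "car_flag": car,
    })
    for a in amplicons:
        col = []
        for pat in patterns:
            if isinstance(pat, dict):        # explicit calls incl. NaN
                col.append(pat.get(a, 0.0))
            else:
                col.append(1.0 if a in pat else 0.0)
        df[a] = col
    return df


@pytest.fixture(scope="session")
def small_cohort():
    cfg = SimulationConfig(n_patients=12, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
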