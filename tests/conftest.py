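"""Shared fixtures: simulated colonies at the study's conditions.

The "recovery" colonies reproduce the scaled benchmark used throughout:
16 chromosomes totalling ~20 Mb (chromosome proportions of the honey-bee
assembly), 314 bp marker spacing, 37.1 cM/Mb, 15 drones and 6 workers,
error-free and CNV-free so that phasing and event recovery can be scored
exactly against the truth set.
"""

from __future__ import annotations

import numpy as np
import pytest

from dronemap.pipeline import analyze_colony
from dronemap.simulate import SimulationConfig, simulate_colony

N_RECOVERY_COLONIES = 20
SCALE = 1 / 11


def recovery_config(seed: int) -> SimulationConfig:
    return SimulationConfig().scaled(
        SCALE,
        seed=seed,
        genotype_error_rate=0.0,
        cnv_fraction=0.0,
    )


@pytest.fixture(scope="session")
def recovery_colonies():
    """Twenty analyzed error-free colonies with truth sets (criteria bench)."""
    out = []
    for seed in range(N_RECOVERY_COLONIES):
        colony = simulate_colony(recovery_config(seed))
        results = analyze_colony(colony, error_tolerance=0)
        out.append((colony, results))
    return out


@pytest.fixture(scope="session")
def clean_colony(recovery_colonies):
    """One error-free colony plus its pipeline results."""
    return recovery_colonies[0]


@pytest.fixture(scope="session")
def noisy_colony():
    """A colony with CNV regions and genotyping errors (default conditions)."""
    cfg = SimulationConfig().scaled(1 / 11, seed=101)
    colony = simulate_colony(cfg)
    results = analyze_colony(colony)
    return colony, results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
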