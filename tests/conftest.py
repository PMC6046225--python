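"""Shared fixtures: a reduced-scale synthetic study for unit tests.

The full-scale study conditions live in ``SimulationParams`` defaults;
unit tests run on a smaller cohort for speed and only the acceptance
tests exercise the full scale.
"""

import logging

import pytest

from senesplice.model import AnalysisConfig
from senesplice.simulate import SimulationParams, simulate_study

logging.getLogger("senesplice").setLevel(logging.ERROR)


def small_params(seed: int = 0, **overrides) -> SimulationParams:
    base = dict(
        seed=seed,
        n_experiments=6,
        n_genes=300,
        n_rbps=8,
        n_events=60,
        n_true_regulators=2,
        rbp_down_fraction=0.375,
        n_affected_experiments=4,
        n_variants=20,
        n_gene_sets=10,
        n_decoy_peaks_per_rbp=5,
    )
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_params(seed=11))


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig(seed=11)
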