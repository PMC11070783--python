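"""Shared fixtures: simulated recordings processed through the pipeline.

Full 14-day simulations are session-scoped because several test modules and
the acceptance suite reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import gryllometry as g


@dataclass
class Processed:
    """A simulation together with its pipeline products."""

    sim: g.SimResult
    track: g.TrackTable  # filtered + imputed
    qc: g.QcReport
    ethogram: g.Ethogram


def _process(sim: g.SimResult) -> Processed:
    filtered, qc = g.filter_by_likelihood(
        sim.track, sim.config.likelihood_threshold, sim.config
    )
    imputed = g.impute_missing(filtered)
    eth = g.classify(imputed, sim.config)
    return Processed(sim=sim, track=imputed, qc=qc, ethogram=eth)


@pytest.fixture(scope="session")
def sim_default() -> g.SimResult:
    """14-day simulation at the default study conditions, seed 0."""
    return g.simulate(g.default_paper_params(), seed=0)


@pytest.fixture(scope="session")
def pipeline_default(sim_default) -> Processed:
    return _process(sim_default)


@pytest.fixture(scope="session")
def pipeline_lownoise() -> Processed:
    """14-day simulation at 0.5 px keypoint noise (classifier-fidelity tests)."""
    params = g.default_paper_params()
    params.keypoint_noise_sd = 0.5
    return _process(g.simulate(params, seed=1))


@pytest.fixture(scope="session")
def sim_small() -> g.SimResult:
    """2-day simulation for cheap structural tests."""
    return g.simulate(g.SimParams(days=2), seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
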