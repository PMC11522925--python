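"""Shared fixtures: the toy enzyme/polymer system and small trajectories."""
from __future__ import annotations

import numpy as np
import pytest

from entryscope import synthcase as sc
from entryscope.model_io import AnalysisConfig


@pytest.fixture(scope="session")
def toy():
    """Toy system (40 residues, 5 polymer units) and reference coordinates."""
    spec = sc.FixtureSpec(seed=1, n_residues=40, n_polymer_units=5,
                          n_frames=120, noise=0.3)
    system, ref = sc.make_toy_system(spec)
    return spec, system, ref


@pytest.fixture(scope="session")
def small_toy():
    """Smaller system for brute-force oracle comparisons."""
    spec = sc.FixtureSpec(seed=4, n_residues=10, n_polymer_units=3,
                          n_frames=20, noise=0.2)
    system, ref = sc.make_toy_system(spec)
    return spec, system, ref


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def noiseless_entry(toy):
    spec, system, ref = toy
    quiet = sc.FixtureSpec(seed=spec.seed, n_residues=spec.n_residues,
                           n_polymer_units=spec.n_polymer_units,
                           n_frames=spec.n_frames, noise=0.0)
    traj, truth, corridor = sc.simulate_entry(system, ref, quiet, corridor=2,
                                              seed=11)
    return system, traj, truth, corridor
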