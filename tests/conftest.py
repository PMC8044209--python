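"""Shared fixtures: synthetic truths, PRE profiles and the ensemble-size scan.

The three-state scan is the expensive end-to-end computation (6 sizes × 4
starting models × 10 replicates); it is built once per session and shared by
the acceptance test and the ensemble property tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import fuzzyfit as ff
from fuzzyfit.simulate import SyntheticTruth, simulate_pre

TRUTH_SEED = 3
SCAN_SEED = 11


def profiles_for(truth: SyntheticTruth) -> list:
    pairs = simulate_pre(truth)
    profs = []
    for site, sat in zip(truth.label_sites, truth.saturations):
        para, dia = pairs[site.label_id]
        profs.append(ff.pre_profile(para, dia, site, saturation=sat))
    return profs


@pytest.fixture(scope="session")
def three_state_truth() -> SyntheticTruth:
    """Three-state fuzzy truth at the default study design (5% noise, 3 sites)."""
    return SyntheticTruth(seed=TRUTH_SEED, true_n_states=3)


@pytest.fixture(scope="session")
def three_state_profiles(three_state_truth):
    return profiles_for(three_state_truth)


@pytest.fixture(scope="session")
def three_state_model(three_state_truth, three_state_profiles):
    return ff.PREEnsembleModel(three_state_profiles, three_state_truth.partner,
                               three_state_truth.ligand,
                               three_state_truth.forward_params)


@pytest.fixture(scope="session")
def three_state_scan(three_state_model):
    """Sizes 1-6, 4 starting models × 10 replicates (the scaled-down scan)."""
    return three_state_model.size_scan(sizes=range(1, 7), replicates=10,
                                       starting_models=4, seed=SCAN_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
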