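"""Shared fixtures: small stimuli and a cached minimal-circuit pipeline run.

The fig1-style pipeline (4 OFF LNP cells onto one LIF cell under binary
white noise) is expensive enough that several test modules share one
module-scoped run of it.
"""

from __future__ import annotations

import numpy as np
import pytest

import stnmflab as sl


@pytest.fixture(scope="session")
def small_movie():
    return sl.generate_white_noise(2000, (8, 8), 10.0, seed=42)


@pytest.fixture(scope="session")
def fig1_run():
    """A medium-sized fig1 simulation + STNMF, shared across tests.

    Returns dict with spec, movie, trains, effective images, stnmf result
    and the truth-matched (rgc order) module permutation.
    """
    spec = sl.preset_network("fig1")
    movie = sl.generate_white_noise(60_000, (8, 8), 10.0, seed=7)
    trains = sl.simulate_network(spec, movie, seed=8)
    eff = sl.effective_images(movie, trains["lgn"], n_lags=15)
    result = sl.semi_nmf(eff, sl.STNMFConfig(K=4, seed=9, n_restarts=4))
    truth = [spec.cells[c].filter.spatial for c in spec.lnp_ids]
    sim = sl.rf_similarity_matrix(truth, list(result.module_images()))
    rows, cols, scores = sl.hungarian_match(sim)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols  # perm[i] = module index matched to rgc i
    return {
        "spec": spec,
        "movie": movie,
        "trains": trains,
        "eff": eff,
        "result": result,
        "truth": truth,
        "perm": perm,
        "match_cosines": np.abs(scores),
    }
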