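"""Shared fixtures: small synthetic worlds used across the test modules."""

from __future__ import annotations

import os

# single-threaded BLAS: reproducible arithmetic, and small-matrix GEMMs
# are faster without thread fan-out
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from synprof import synthetic as syn


@pytest.fixture(scope="session")
def small_library():
    """A 40-drug library, enough for pair-level statistics."""
    return syn.simulate_compound_library(
        n_compounds=40, n_bits=128, n_targets=13, sparsity=0.2, seed=11
    )


@pytest.fixture(scope="session")
def panel():
    return syn.simulate_cell_lines(n_lines=5, n_genes=7, seed=12)


@pytest.fixture(scope="session")
def motifs():
    return syn.default_motifs(n_lines=5)


@pytest.fixture(scope="session")
def small_table(small_library, panel, motifs):
    return syn.simulate_synergy_table(
        small_library, panel, motifs, n_pairs_per_line=150, noise_sd=0.5, seed=13
    )


@pytest.fixture(scope="session")
def profiles(small_library):
    return small_library.latent_profile_frame()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
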