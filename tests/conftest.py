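"""Shared fixtures: small deterministic datasets and reference model parameters."""

import numpy as np
import pytest

import dyadseq as dq

# Reference 4x4 transition matrix over the joint states
# (NONE, A_ONLY, B_ONLY, BOTH); rows sum to 1.
REF_TRANSITION = np.array(
    [
        [0.79, 0.06, 0.06, 0.10],
        [0.19, 0.33, 0.08, 0.40],
        [0.32, 0.05, 0.31, 0.32],
        [0.05, 0.08, 0.06, 0.80],
    ]
)

# The reference rows carry 2-decimal rounding (sums 1.01 / 0.99);
# simulations need exactly stochastic rows, so a row-normalized copy is used
# wherever data are generated.
REF_TRANSITION_NORM = REF_TRANSITION / REF_TRANSITION.sum(axis=1, keepdims=True)

# Reference 2-latent-state HMM: state 0 ("stress unresolved") is left for
# state 1 ("stress solved"), which is absorbing.
REF_HMM_INITIAL = np.array([1.0, 0.0])
REF_HMM_TRANSITION = np.array([[0.97, 0.03], [0.0, 1.0]])
REF_HMM_EMISSION = np.array(
    [
        [0.07, 0.09, 0.07, 0.77],
        [0.65, 0.09, 0.12, 0.14],
    ]
)
REF_HMM_MASK = np.array([[False, False], [True, False]])

# Reference 2-class mixture of Markov chains.
REF_MIX_WEIGHTS = np.array([0.59, 0.41])
REF_MIX_TRANSITION = np.array(
    [
        [
            [0.86, 0.05, 0.06, 0.03],
            [0.23, 0.41, 0.02, 0.34],
            [0.37, 0.03, 0.35, 0.25],
            [0.11, 0.16, 0.12, 0.61],
        ],
        [
            [0.58, 0.08, 0.11, 0.23],
            [0.13, 0.26, 0.10, 0.51],
            [0.20, 0.05, 0.25, 0.50],
            [0.02, 0.04, 0.04, 0.90],
        ],
    ]
)
REF_MIX_INITIAL = np.array([[0.05, 0.05, 0.05, 0.85], [0.05, 0.05, 0.05, 0.85]])

# A single dyad's 4x2 transition-table counts: rows are the joint prior state
# (A=1,B=1), (1,0), (0,1), (0,0); columns are (target shown, not shown).
SINGLE_DYAD_COUNTS = np.array([[23, 4], [1, 1], [3, 1], [3, 11]], dtype=float)


@pytest.fixture
def ref_transition():
    return REF_TRANSITION.copy()


@pytest.fixture
def small_dataset():
    """Six hand-written dyads, fixed content, no dropout (T = 6)."""
    rows = [
        ("d1", [1, 1, 0, 1, 0, 0], [1, 0, 0, 1, 1, 0]),
        ("d2", [0, 0, 1, 1, 1, 0], [0, 1, 1, 1, 0, 0]),
        ("d3", [1, 1, 1, 1, 1, 1], [1, 1, 1, 0, 1, 1]),
        ("d4", [0, 0, 0, 0, 1, 0], [0, 0, 1, 0, 0, 0]),
        ("d5", [1, 0, 1, 0, 1, 0], [0, 1, 0, 1, 0, 1]),
        ("d6", [1, 1, 0, 0, 1, 1], [1, 1, 1, 1, 0, 0]),
    ]
    pairs = [
        dq.DyadSequencePair(i, np.array(a), np.array(b), {"satisfaction": k + 1.0})
        for k, (i, a, b) in enumerate(rows)
    ]
    return dq.Dataset(pairs, label_a="SC", label_b="DC")


@pytest.fixture
def markov_dataset():
    """64 x 48 dataset simulated from the reference transition matrix."""
    model = dq.MarkovModel(
        initial=np.array([0.02, 0.03, 0.03, 0.92]), transition=REF_TRANSITION_NORM
    )
    return dq.simulate_markov(model, dq.SimulationSpec(seed=7))
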