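"""Synthetic dyadic-sequence generators for every model family.

These generators emulate the kind of data produced by interval-sampled couple
observations: by default 64 dyads x 48 intervals of two interdependent binary
streams (one per partner).  Each generator draws the joint 4-state sequence
from a fully specified process — basic Markov, hidden Markov, mixture Markov,
or a lag-1 logit actor-partner process — and collapses it back to the two
binary streams, so every emitted dataset passes the same validation as read
data.  They serve as the test bed for parameter recovery and as inputs to the
design helpers.

All randomness flows through one seeded generator per dataset, consumed in
dyad order, so results are bit-identical given the seed.  An optional
geometric dropout time can truncate sequences (off by default: the emulated
study design, a short waiting condition, makes dropout unlikely).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logit_apim import LogitParams
from .markov import HiddenMarkovModel, MarkovModel, MixtureMarkovModel, _check_stochastic
from .seqdata import N_STATES, Dataset, StateSequence, collapse_states

# Study-like defaults: 64 couples observed over 48 intervals of 10 s, with
# nearly all couples starting in the joint "both behaviors shown" state.
DEFAULT_N_DYADS = 64
DEFAULT_T = 48
DEFAULT_INITIAL = np.array([0.02, 0.03, 0.03, 0.92])


@dataclass
class SimulationSpec:
    """Size, seed and optional dropout settings for one synthetic dataset."""

    n_dyads: int = DEFAULT_N_DYADS
    t: int = DEFAULT_T
    seed: int | None = None
    dropout_prob: float = 0.0  # per-interval geometric dropout hazard after t=2

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.t < 2:
            raise ValueError("need n_dyads >= 1 and t >= 2")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _maybe_truncate(length: int, spec: SimulationSpec, rng: np.random.Generator) -> int:
    if spec.dropout_prob == 0:
        return length
    # geometric dropout time; at least 2 intervals are always observed
    drop_at = 2 + rng.geometric(spec.dropout_prob)
    return min(length, drop_at)


def _pairs_to_dataset(seqs: list[np.ndarray], label_a: str, label_b: str) -> Dataset:
    pairs = [
        collapse_states(StateSequence(str(i + 1), s)) for i, s in enumerate(seqs)
    ]
    return Dataset(pairs, label_a=label_a, label_b=label_b)


def _simulate_chain(
    initial: np.ndarray, transition: np.ndarray, t: int, rng: np.random.Generator
) -> np.ndarray:
    k = len(initial)
    cum_init = np.cumsum(initial)
    cum_tr = np.cumsum(transition, axis=1)
    s = np.empty(t, dtype=int)
    s[0] = int(np.searchsorted(cum_init, rng.random()))
    u = rng.random(t - 1)
    for i in range(1, t):
        s[i] = int(np.searchsorted(cum_tr[s[i - 1]], u[i - 1]))
    return np.minimum(s, k - 1)


def simulate_markov(
    model: MarkovModel, spec: SimulationSpec, label_a: str = "A", label_b: str = "B"
) -> Dataset:
    """Simulate dyads from a basic Markov chain over the 4 joint states."""
    initial = _check_stochastic(model.initial, "initial")
    transition = _check_stochastic(model.transition, "transition")
    if transition.shape != (N_STATES, N_STATES):
        raise ValueError("transition must be 4 x 4 for the joint state space")
    rng = spec.rng()
    seqs = []
    for _ in range(spec.n_dyads):
        t_obs = _maybe_truncate(spec.t, spec, rng)
        seqs.append(_simulate_chain(initial, transition, t_obs, rng))
    return _pairs_to_dataset(seqs, label_a, label_b)


def simulate_hmm(
    model: HiddenMarkovModel,
    spec: SimulationSpec,
    label_a: str = "A",
    label_b: str = "B",
    return_latent: bool = False,
):
    """Simulate dyads from a hidden Markov model.

    The latent chain is drawn first; each interval's observed joint state is
    then drawn from the emission row of the current latent state.  With
    ``return_latent=True`` the latent traces are returned alongside the data.
    """
    initial = _check_stochastic(model.initial, "initial")
    transition = _check_stochastic(model.transition, "transition")
    emission = _check_stochastic(model.emission, "emission")
    rng = spec.rng()
    seqs, latents = [], []
    cum_emis = np.cumsum(emission, axis=1)
    for _ in range(spec.n_dyads):
        t_obs = _maybe_truncate(spec.t, spec, rng)
        z = _simulate_chain(initial, transition, t_obs, rng)
        u = rng.random(t_obs)
        obs = np.array([int(np.searchsorted(cum_emis[z[i]], u[i])) for i in range(t_obs)])
        obs = np.minimum(obs, N_STATES - 1)
        seqs.append(obs)
        latents.append(z)
    dataset = _pairs_to_dataset(seqs, label_a, label_b)
    if return_latent:
        return dataset, latents
    return dataset


def simulate_mixture(
    model: MixtureMarkovModel,
    spec: SimulationSpec,
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[Dataset, np.ndarray]:
    """Simulate dyads from a mixture of Markov chains.

    A latent class is drawn per dyad, then the dyad's sequence follows that
    class's chain.  Returns the dataset and the true class labels for
    recovery tests.
    """
    weights = _check_stochastic(model.weights, "weights")
    rng = spec.rng()
    cum_w = np.cumsum(weights)
    seqs, classes = [], []
    for _ in range(spec.n_dyads):
        c = int(np.searchsorted(cum_w, rng.random()))
        c = min(c, len(weights) - 1)
        t_obs = _maybe_truncate(spec.t, spec, rng)
        seqs.append(
            _simulate_chain(
                _check_stochastic(model.initial[c], "initial"),
                _check_stochastic(model.transition[c], "transition"),
                t_obs,
                rng,
            )
        )
        classes.append(c)
    return _pairs_to_dataset(seqs, label_a, label_b), np.array(classes)


@dataclass
class CoefficientHeterogeneity:
    """Between-dyad SDs of normal perturbations added to each coefficient.

    One draw per dyad and coefficient, shared by both partners' models
    (common-fate style heterogeneity), so e.g. a positive intercept
    perturbation raises both behaviors' base rates in that dyad.
    """

    b0: float = 0.0
    b_actor: float = 0.0
    b_partner: float = 0.0
    b_ixn: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, self.b_actor, self.b_partner, self.b_ixn])


def simulate_logit_apim(
    params_a: LogitParams,
    params_b: LogitParams,
    spec: SimulationSpec,
    initial: np.ndarray | None = None,
    heterogeneity: CoefficientHeterogeneity | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> Dataset:
    """Simulate dyads from the lag-1 effect-coded logit actor-partner process.

    At each interval t >= 2 the two behaviors are drawn independently from
    Bernoulli(logistic(eta)) where eta uses effect-coded (+/-1) lagged own and
    partner behavior plus their product; the two behaviors are conditionally
    independent given interval t-1.  The first interval is drawn from
    ``initial``, a distribution over the 4 joint states (default: nearly all
    dyads start with both behaviors shown, as after a stress induction).
    """
    if initial is None:
        initial = DEFAULT_INITIAL
    initial = _check_stochastic(initial, "initial")
    base = np.stack([params_a.as_array(), params_b.as_array()])  # (2, 4)
    if not np.isfinite(base).all():
        raise ValueError("coefficients must be finite")
    sd = heterogeneity.as_array() if heterogeneity is not None else np.zeros(4)
    rng = spec.rng()
    cum_init = np.cumsum(initial)
    seqs = []
    for _ in range(spec.n_dyads):
        coef = base + rng.normal(0.0, 1.0, size=4) * sd  # shared dyad-level draw
        t_obs = _maybe_truncate(spec.t, spec, rng)
        s = np.empty(t_obs, dtype=int)
        s0 = min(int(np.searchsorted(cum_init, rng.random())), N_STATES - 1)
        a_prev, b_prev = s0 % 2, s0 // 2
        s[0] = s0
        u = rng.random((t_obs - 1, 2))
        for i in range(1, t_obs):
            ea, eb = 2 * a_prev - 1, 2 * b_prev - 1
            eta_a = coef[0] @ np.array([1.0, ea, eb, ea * eb])
            eta_b = coef[1] @ np.array([1.0, eb, ea, ea * eb])
            a = int(u[i - 1, 0] < 1.0 / (1.0 + np.exp(-eta_a)))
            b = int(u[i - 1, 1] < 1.0 / (1.0 + np.exp(-eta_b)))
            s[i] = a + 2 * b
            a_prev, b_prev = a, b
        seqs.append(s)
    return _pairs_to_dataset(seqs, label_a, label_b)
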