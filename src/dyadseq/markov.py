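"""Basic, hidden and mixture Markov models on expanded 4-state dyad sequences.

The basic (first-order) Markov model treats the joint behavioral state at
interval t as depending only on the state at t-1 (stationarity).  The hidden
Markov model adds a latent chain whose states emit the observed joint states —
the sequence-data analogue of a common-fate process — and supports structural
zero restrictions such as an absorbing "stress solved" state.  The mixture
Markov model assumes latent subgroups of dyads, each with its own transition
matrix, and assigns dyads to classes probabilistically.

All models report a log-likelihood, a free-parameter count and a BIC so that
competing structures can be compared on the same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, xlogy

from .seqdata import N_STATES, StateSequence

# EM settings shared by the hidden and mixture fits.
EM_TOL = 1e-6
EM_MAX_ITER = 500
DEFAULT_RESTARTS = 10


class NonStochasticError(ValueError):
    """A probability vector/matrix does not sum to one (or has negatives)."""


def _check_stochastic(vec_or_mat: np.ndarray, name: str, atol: float = 1e-8) -> np.ndarray:
    arr = np.asarray(vec_or_mat, dtype=float)
    if (arr < -atol).any():
        raise NonStochasticError(f"{name} has negative entries")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise NonStochasticError(f"{name} rows must sum to 1 (got {sums})")
    return arr


@dataclass
class MarkovModel:
    """First-order Markov chain over the 4 joint states."""

    initial: np.ndarray
    transition: np.ndarray
    loglik: float = np.nan
    n_free_params: int = 15  # (4-1) initial + 4 rows x (4-1) transition
    bic: float = np.nan
    n_obs: int = 0  # total observed intervals used for the BIC sample size

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)

    def validate(self) -> "MarkovModel":
        self.initial = _check_stochastic(self.initial, "initial")
        tr = np.asarray(self.transition, dtype=float)
        rows_ok = ~np.isnan(tr).any(axis=1)
        _check_stochastic(tr[rows_ok], "transition")
        self.transition = tr
        return self


@dataclass
class HiddenMarkovModel:
    """Hidden Markov model with K latent states and 4 observed symbols."""

    initial: np.ndarray
    transition: np.ndarray
    emission: np.ndarray
    zero_mask: np.ndarray | None = None  # True where the transition is fixed at 0
    loglik: float = np.nan
    n_free_params: int = 0
    bic: float = np.nan
    n_obs: int = 0
    n_restarts: int = 0
    seed: int | None = None
    converged: bool = True
    loglik_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)

    @property
    def k(self) -> int:
        return len(self.initial)


@dataclass
class MixtureMarkovModel:
    """Mixture of Markov chains: latent dyad classes with class-specific dynamics."""

    weights: np.ndarray
    initial: np.ndarray  # (K, 4)
    transition: np.ndarray  # (K, 4, 4)
    posterior: np.ndarray  # (n_dyads, K)
    loglik: float = np.nan
    n_free_params: int = 0
    bic: float = np.nan
    n_obs: int = 0
    converged: bool = True
    loglik_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)

    @property
    def k_classes(self) -> int:
        return len(self.weights)

    @property
    def hard_labels(self) -> np.ndarray:
        return self.posterior.argmax(axis=1)


@dataclass
class ConditionalEffects:
    """Conditional actor and partner effects read off a transition matrix.

    Each value is the probability that the focal behavior is shown at t, given
    the focal partner's own prior display (actor) or the other partner's prior
    display (partner), conditional on what the other/own behavior was at t-1.
    """

    actor_a_given_b_absent: float
    actor_a_given_b_present: float
    actor_b_given_a_absent: float
    actor_b_given_a_present: float
    partner_a_given_a_absent: float
    partner_a_given_a_present: float
    partner_b_given_b_absent: float
    partner_b_given_b_present: float


# ---------------------------------------------------------------------------
# Sufficient statistics


def _as_state_arrays(state_seqs: list[StateSequence]) -> list[np.ndarray]:
    return [np.asarray(s.states, dtype=int) for s in state_seqs]


def transition_counts(state_seqs: list[StateSequence]) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled first-state counts, transition counts and total interval count."""
    first = np.zeros(N_STATES)
    counts = np.zeros((N_STATES, N_STATES))
    n_obs = 0
    for s in _as_state_arrays(state_seqs):
        first[s[0]] += 1
        np.add.at(counts, (s[:-1], s[1:]), 1)
        n_obs += len(s)
    return first, counts, n_obs


# ---------------------------------------------------------------------------
# Basic Markov model


def fit_markov(state_seqs: list[StateSequence]) -> MarkovModel:
    """Maximum-likelihood fit of the basic Markov model.

    The transition matrix is the row-normalized pooled transition count table;
    the initial distribution is the empirical distribution of first states.
    Rows for prior states never visited are reported as NaN with a warning.
    """
    if not state_seqs:
        raise ValueError("need at least one sequence")
    first, counts, n_obs = transition_counts(state_seqs)
    initial = first / first.sum()
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        transition = counts / row_sums[:, None]
    empty = row_sums == 0
    if empty.any():
        warnings.warn(
            f"prior states never visited: {np.nonzero(empty)[0].tolist()}; "
            "their transition rows are undefined (NaN)",
            stacklevel=2,
        )
        transition[empty] = np.nan
    loglik = float(xlogy(first, initial).sum() + xlogy(counts, np.where(np.isnan(transition), 1, transition)).sum())
    model = MarkovModel(initial=initial, transition=transition, loglik=loglik, n_obs=n_obs)
    model.bic = bic(loglik, model.n_free_params, n_obs)
    return model


def markov_loglik(model: MarkovModel, state_seqs: list[StateSequence]) -> float:
    """Log-likelihood of sequences under a given basic Markov model."""
    ll = 0.0
    with np.errstate(divide="ignore"):
        log_init = np.log(model.initial)
        log_tr = np.log(model.transition)
    for s in _as_state_arrays(state_seqs):
        ll += log_init[s[0]] + log_tr[s[:-1], s[1:]].sum()
    return float(ll)


def conditional_effects(model: MarkovModel) -> ConditionalEffects:
    """Actor and partner effects as sums of transition probabilities.

    The actor effect for partner A is the probability of A showing the
    behavior at t given A showed it at t-1, i.e. the sum of transitions from
    the conditioning row into the two states that contain A's behavior
    (A_ONLY and BOTH); the conditioning row is A_ONLY or BOTH depending on
    whether B's behavior was absent or present at t-1.  Partner effects
    condition on the *other* partner's prior display instead.
    """
    p = model.transition
    into_a = p[:, 1] + p[:, 3]  # probability of moving into a state containing A
    into_b = p[:, 2] + p[:, 3]
    return ConditionalEffects(
        actor_a_given_b_absent=float(into_a[1]),
        actor_a_given_b_present=float(into_a[3]),
        actor_b_given_a_absent=float(into_b[2]),
        actor_b_given_a_present=float(into_b[3]),
        partner_a_given_a_absent=float(into_a[2]),
        partner_a_given_a_present=float(into_a[3]),
        partner_b_given_b_absent=float(into_b[1]),
        partner_b_given_b_present=float(into_b[3]),
    )


# ---------------------------------------------------------------------------
# Hidden Markov model (Baum-Welch)


def _group_by_length(seqs: list[np.ndarray]) -> dict[int, np.ndarray]:
    groups: dict[int, list[np.ndarray]] = {}
    for s in seqs:
        groups.setdefault(len(s), []).append(s)
    return {t: np.stack(g) for t, g in groups.items()}


def _hmm_e_step(obs: np.ndarray, initial, transition, emission):
    """Scaled forward-backward for a batch of equal-length sequences.

    Returns (loglik, first-state posteriors summed, expected transition
    counts, expected emission counts), all summed over the batch.
    """
    n, t_len = obs.shape
    k = len(initial)
    b = emission[:, obs]  # (K, n, T)
    alpha = np.empty((t_len, n, k))
    scale = np.empty((t_len, n))
    a = initial[None, :] * b[:, :, 0].T
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ transition) * b[:, :, t].T
        scale[t] = a.sum(axis=1)
        alpha[t] = a / scale[t][:, None]
    loglik = float(np.log(scale).sum())

    beta = np.empty((t_len, n, k))
    beta[-1] = 1.0
    xi_sum = np.zeros((k, k))
    for t in range(t_len - 2, -1, -1):
        bb = b[:, :, t + 1].T * beta[t + 1]  # (n, K)
        # expected transitions t -> t+1, summed over batch
        xi_sum += np.einsum("ni,ij,nj->ij", alpha[t], transition, bb / scale[t + 1][:, None])
        beta[t] = (bb / scale[t + 1][:, None]) @ transition.T
    gamma = alpha * beta  # (T, n, K), rows sum to 1
    first = gamma[0].sum(axis=0)
    emis = np.einsum("tnk,tnm->km", gamma, np.eye(N_STATES)[obs.T])
    return loglik, first, xi_sum, emis, gamma


def hmm_loglik(model: HiddenMarkovModel, state_seqs: list[StateSequence]) -> float:
    """Log-likelihood of sequences under a fitted HMM (scaled forward pass)."""
    total = 0.0
    for t_len, obs in _group_by_length(_as_state_arrays(state_seqs)).items():
        ll, *_ = _hmm_e_step(obs, model.initial, model.transition, model.emission)
        total += ll
    return float(total)


def _dirichlet_rows(rng: np.random.Generator, shape, mask=None) -> np.ndarray:
    """Random stochastic rows; entries under ``mask`` are fixed to exact zero."""
    out = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1])
    if mask is not None:
        out = np.where(mask, 0.0, out)
        out /= out.sum(axis=-1, keepdims=True)
    return out


def hmm_free_params(k: int, zero_mask: np.ndarray | None) -> int:
    """Free parameters: (K-1) initial + unfixed transition entries (one per
    row is determined by the sum constraint) + K*(4-1) emission."""
    if zero_mask is None:
        n_tr = k * (k - 1)
    else:
        n_tr = int((~zero_mask).sum()) - k
    return (k - 1) + n_tr + k * (N_STATES - 1)


def fit_hmm(
    state_seqs: list[StateSequence],
    k: int,
    zero_mask: np.ndarray | None = None,
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HiddenMarkovModel:
    """Baum-Welch EM fit of a K-state HMM over the 4 observed joint states.

    ``zero_mask`` is a boolean K x K matrix marking transitions fixed at zero
    (e.g. into a left absorbing state); EM's multiplicative updates preserve
    exact zeros, so masked cells stay zero throughout.  The best of
    ``restarts`` seeded random initializations is returned.  Latent states are
    canonicalized by descending initial probability unless a mask pins the
    indexing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seqs = _as_state_arrays(state_seqs)
    if k > len(set(np.concatenate(seqs).tolist())):
        warnings.warn("more latent states than distinct observed states", stacklevel=2)
    if zero_mask is not None:
        zero_mask = np.asarray(zero_mask, dtype=bool)
        if zero_mask.shape != (k, k):
            raise ValueError("zero_mask must be K x K")
        if zero_mask.all(axis=1).any():
            raise ValueError("zero_mask forbids all transitions out of a state")
    groups = _group_by_length(seqs)
    n_obs = sum(len(s) for s in seqs)
    rng = np.random.default_rng(seed)

    best: HiddenMarkovModel | None = None
    for _ in range(max(1, restarts)):
        initial = _dirichlet_rows(rng, (k,))
        transition = _dirichlet_rows(rng, (k, k), zero_mask)
        emission = _dirichlet_rows(rng, (k, N_STATES))
        history: list[float] = []
        prev = -np.inf
        converged = False
        for _it in range(max_iter):
            ll = 0.0
            first = np.zeros(k)
            xi = np.zeros((k, k))
            emis = np.zeros((k, N_STATES))
            n_first = 0
            for obs in groups.values():
                l, f, x, e, _ = _hmm_e_step(obs, initial, transition, emission)
                ll += l
                first += f
                xi += x
                emis += e
                n_first += len(obs)
            history.append(ll)
            if ll + 1e-9 < prev:  # EM guarantees monotone loglik
                raise AssertionError(f"EM log-likelihood decreased: {prev} -> {ll}")
            if np.isfinite(prev) and abs(ll - prev) < tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = ll
            initial = first / n_first
            with np.errstate(invalid="ignore"):
                transition = xi / xi.sum(axis=1, keepdims=True)
            transition = np.nan_to_num(transition, nan=0.0)
            # keep rows stochastic even when a state gets no expected visits
            dead = transition.sum(axis=1) == 0
            if dead.any():
                transition[dead] = (
                    np.where(zero_mask[dead], 0.0, 1.0) if zero_mask is not None else 1.0
                )
                transition[dead] /= transition[dead].sum(axis=1, keepdims=True)
            emission = emis / emis.sum(axis=1, keepdims=True)
            if zero_mask is not None:
                transition[zero_mask] = 0.0
        if best is None or history[-1] > best.loglik:
            best = HiddenMarkovModel(
                initial=initial,
                transition=transition,
                emission=emission,
                zero_mask=zero_mask,
                loglik=history[-1],
                n_obs=n_obs,
                n_restarts=restarts,
                seed=seed,
                converged=converged,
                loglik_history=history,
            )
    assert best is not None
    if zero_mask is None:
        # canonical order: descending initial probability, ties by first
        # transition-row lexicographic order
        order = np.lexsort((-best.transition[:, 0], -best.initial))
        best.initial = best.initial[order]
        best.transition = best.transition[np.ix_(order, order)]
        best.emission = best.emission[order]
    best.n_free_params = hmm_free_params(k, zero_mask)
    best.bic = bic(best.loglik, best.n_free_params, n_obs)
    return best


# ---------------------------------------------------------------------------
# Mixture Markov model


def fit_mixture(
    state_seqs: list[StateSequence],
    k_classes: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> MixtureMarkovModel:
    """EM fit of a K-class mixture of Markov chains over dyads.

    With one class this is exactly the basic Markov model.  Classes are
    reported sorted by descending weight.
    """
    if k_classes < 1:
        raise ValueError("k_classes must be >= 1")
    seqs = _as_state_arrays(state_seqs)
    n = len(seqs)
    n_obs = sum(len(s) for s in seqs)
    # per-dyad sufficient statistics
    firsts = np.zeros((n, N_STATES))
    counts = np.zeros((n, N_STATES, N_STATES))
    for i, s in enumerate(seqs):
        firsts[i, s[0]] = 1
        np.add.at(counts[i], (s[:-1], s[1:]), 1)
    rng = np.random.default_rng(seed)

    best: MixtureMarkovModel | None = None
    for _ in range(max(1, restarts)):
        weights = _dirichlet_rows(rng, (k_classes,))
        initial = _dirichlet_rows(rng, (k_classes, N_STATES))
        transition = _dirichlet_rows(rng, (k_classes, N_STATES, N_STATES))
        history: list[float] = []
        prev = -np.inf
        converged = False
        post = np.full((n, k_classes), 1.0 / k_classes)
        for _it in range(max_iter):
            with np.errstate(divide="ignore"):
                log_w = np.log(weights)
                log_pi = np.log(initial)
                log_a = np.log(transition)
            # -inf is clipped so that 0-count cells with 0 probability
            # contribute 0 rather than NaN; cells with positive counts and
            # zero probability still get an effectively -inf responsibility
            log_pi = np.maximum(log_pi, -1e30)
            log_a = np.maximum(log_a, -1e30)
            log_r = (
                log_w[None, :]
                + np.einsum("ns,ks->nk", firsts, log_pi)
                + np.einsum("nij,kij->nk", counts, log_a)
            )
            ll = float(logsumexp(log_r, axis=1).sum())
            history.append(ll)
            if ll + 1e-9 < prev:
                raise AssertionError(f"EM log-likelihood decreased: {prev} -> {ll}")
            if np.isfinite(prev) and abs(ll - prev) < tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = ll
            post = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
            resp = post.sum(axis=0)
            weights = resp / n
            initial = (post.T @ firsts) / resp[:, None]
            trans_counts = np.einsum("nk,nij->kij", post, counts)
            row = trans_counts.sum(axis=2, keepdims=True)
            with np.errstate(invalid="ignore"):
                transition = np.where(row > 0, trans_counts / np.where(row == 0, 1, row), 1.0 / N_STATES)
        if (weights < 1e-6).any():
            warnings.warn("mixture contains a near-empty class", stacklevel=2)
        if best is None or history[-1] > best.loglik:
            best = MixtureMarkovModel(
                weights=weights,
                initial=initial,
                transition=transition,
                posterior=post,
                loglik=history[-1],
                n_obs=n_obs,
                converged=converged,
                loglik_history=history,
            )
    assert best is not None
    order = np.argsort(-best.weights, kind="stable")
    best.weights = best.weights[order]
    best.initial = best.initial[order]
    best.transition = best.transition[order]
    best.posterior = best.posterior[:, order]
    best.n_free_params = (k_classes - 1) + k_classes * 15
    best.bic = bic(best.loglik, best.n_free_params, n_obs)
    return best


# ---------------------------------------------------------------------------
# Model comparison


def bic(loglik: float, n_free_params: int, n: int) -> float:
    """Bayesian information criterion, -2 loglik + k ln(n); lower is better.

    The sample size n is the total number of observed intervals across
    sequences (the likelihood includes the initial-state terms).
    """
    return float(-2.0 * loglik + n_free_params * np.log(n))


def compare_bic(models: list, names: list[str] | None = None):
    """Rank fitted models by BIC; all must be fitted on the same data.

    The data fingerprint used is the total observed interval count.
    """
    import pandas as pd

    n_obs = {m.n_obs for m in models}
    if len(n_obs) > 1:
        raise ValueError(f"models were fitted on different data (n_obs: {sorted(n_obs)})")
    if names is None:
        names = [type(m).__name__ for m in models]
    table = pd.DataFrame(
        {
            "model": names,
            "loglik": [m.loglik for m in models],
            "n_free_params": [m.n_free_params for m in models],
            "bic": [m.bic for m in models],
        }
    ).sort_values("bic", kind="stable", ignore_index=True)
    table["best"] = table["bic"] == table["bic"].min()
    return table
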