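"""Study-design helpers: zero/low-frequency cell simulation and power analysis.

The aggregated logit approach breaks down when a dyad's 4 x 2 state-transition
table contains zero (or very low) cell frequencies, which becomes likely when
the number of observation intervals is small relative to the rarest expected
cell.  ``est_freq`` simulates, for a given expected cell-probability table and
interval count, how many zero and low-frequency cells to expect per dyad;
``est_time`` inverts this to the smallest interval count whose expected
problem-cell count is tolerable.

``sample_size_t`` and ``sample_size_correlation`` give the number of
observation units needed for the across-dyad inference steps: exact
noncentral-t power for one- and two-sample t-tests, and the Fisher-z
approximation for correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

N_CELLS = 8  # 4 joint prior states x 2 outcomes


@dataclass
class CellDesign:
    """Expected transition-table cell probabilities and simulation settings.

    ``cell_probs`` is the 4 x 2 table of expected cell proportions (sums to
    1).  Each simulated dyad draws its table as ``n_draws`` i.i.d. multinomial
    assignments; by default one draw per transition, i.e. T - 1.
    """

    cell_probs: np.ndarray
    t: int = 48
    low_threshold: int = 5
    n_sims: int = 10_000
    seed: int | None = None
    n_draws: int | None = None  # override the default T - 1 draws

    def __post_init__(self) -> None:
        self.cell_probs = np.asarray(self.cell_probs, dtype=float)
        if self.cell_probs.size != N_CELLS:
            raise ValueError("cell_probs must have 8 entries (4 x 2)")
        if (self.cell_probs < 0).any() or not np.isclose(self.cell_probs.sum(), 1.0):
            raise ValueError("cell_probs must be nonnegative and sum to 1")
        if self.t < 2:
            raise ValueError("t must be >= 2")

    @property
    def draws(self) -> int:
        return self.n_draws if self.n_draws is not None else self.t - 1


@dataclass
class CellFrequencyResult:
    expected_zero_cells: float
    expected_low_cells: float
    zero_distribution: np.ndarray  # P(#zero cells = 0..8)
    low_distribution: np.ndarray
    mc_se_zero: float
    mc_se_low: float


def est_freq(design: CellDesign) -> CellFrequencyResult:
    """Simulate the expected number of zero and low-frequency table cells.

    Each simulation draws ``design.draws`` cell assignments i.i.d. from the
    expected cell probabilities and counts cells with frequency 0 and with
    frequency below ``low_threshold``.  Returns means over simulations, the
    full count distributions and Monte Carlo standard errors.
    """
    rng = np.random.default_rng(design.seed)
    probs = design.cell_probs.ravel()
    counts = rng.multinomial(design.draws, probs, size=design.n_sims)
    n_zero = (counts == 0).sum(axis=1)
    n_low = (counts < design.low_threshold).sum(axis=1)
    zero_dist = np.bincount(n_zero, minlength=N_CELLS + 1)[: N_CELLS + 1] / design.n_sims
    low_dist = np.bincount(n_low, minlength=N_CELLS + 1)[: N_CELLS + 1] / design.n_sims
    return CellFrequencyResult(
        expected_zero_cells=float(n_zero.mean()),
        expected_low_cells=float(n_low.mean()),
        zero_distribution=zero_dist,
        low_distribution=low_dist,
        mc_se_zero=float(n_zero.std(ddof=1) / np.sqrt(design.n_sims)),
        mc_se_low=float(n_low.std(ddof=1) / np.sqrt(design.n_sims)),
    )


def est_time(
    cell_probs: np.ndarray,
    tolerance: float,
    which: str = "zero",
    low_threshold: int = 5,
    n_sims: int = 10_000,
    seed: int | None = None,
    t_max: int = 100_000,
) -> int:
    """Smallest T whose expected problem-cell count is at most ``tolerance``.

    Uses common random numbers across candidate T: one stream of i.i.d. cell
    assignments is drawn once, and the expected count for any T uses its first
    T - 1 draws, which makes the expected count non-increasing in T and the
    doubling-plus-bisection search self-consistent.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if which not in ("zero", "low"):
        raise ValueError("which must be 'zero' or 'low'")
    probs = np.asarray(cell_probs, dtype=float).ravel()
    design = CellDesign(cell_probs=probs, t=2)  # validates probs
    structural_zero = probs == 0
    if which == "zero" and structural_zero.any() and tolerance < structural_zero.sum():
        raise ValueError(
            f"infeasible: {int(structural_zero.sum())} cells have zero probability "
            "and will always have zero frequency"
        )
    rng = np.random.default_rng(seed)
    threshold = 1 if which == "zero" else low_threshold

    draws = None  # (n_sims, current_max_draws) cumulative cell counts, built lazily
    cells = np.arange(N_CELLS)

    def expected(t: int) -> float:
        nonlocal draws
        need = t - 1
        if draws is None or draws.shape[1] < need:
            extra = need if draws is None else need - draws.shape[1]
            new = rng.choice(cells, size=(n_sims, extra), p=probs)
            draws = new if draws is None else np.concatenate([draws, new], axis=1)
        counts = np.stack(
            [(draws[:, :need] == c).sum(axis=1) for c in range(N_CELLS)], axis=1
        )
        return float((counts < threshold).sum(axis=1).mean())

    lo = 2
    if expected(lo) <= tolerance:
        return lo
    hi = 4
    while expected(hi) > tolerance:
        lo = hi
        hi *= 2
        if hi > t_max:
            raise ValueError(f"tolerance not reached below T = {t_max}")
    # invariant: expected(lo) > tolerance >= expected(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected(mid) > tolerance:
            lo = mid
        else:
            hi = mid
    return hi


# ---------------------------------------------------------------------------
# Power analysis


@dataclass
class PowerQuery:
    """Effect size, error rates and design for a sample-size calculation."""

    effect: float
    alpha: float = 0.05
    power: float = 0.80
    tails: int = 2
    design: str = "one_sample_t"  # one_sample_t | two_sample_t | correlation

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.design not in ("one_sample_t", "two_sample_t", "correlation"):
            raise ValueError(f"unknown design {self.design!r}")


def t_test_power(d: float, n: int, alpha: float = 0.05, tails: int = 2, design: str = "one_sample_t") -> float:
    """Exact power of a t-test from the noncentral t distribution.

    For the two-sample design ``n`` is the per-group size (equal groups).
    """
    d = abs(d)
    if design == "one_sample_t":
        df, ncp = n - 1, d * np.sqrt(n)
    elif design == "two_sample_t":
        df, ncp = 2 * n - 2, d * np.sqrt(n / 2.0)
    else:
        raise ValueError(f"unknown t design {design!r}")
    if df < 1:
        return 0.0
    crit = stats.t.ppf(1 - alpha / tails, df)
    power = stats.nct.sf(crit, df, ncp)
    if tails == 2:
        power += stats.nct.cdf(-crit, df, ncp)
    return float(power)


def _smallest_n(power_fn, target: float, n_min: int) -> int:
    lo, hi = n_min, n_min
    while power_fn(hi) < target:
        lo = hi
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("required sample size exceeds search bound")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return hi


def sample_size_t(query: PowerQuery) -> dict[str, int]:
    """Smallest sample size reaching the target power for a t-test.

    One-sample: returns the total N.  Two-sample (equal groups): returns the
    per-group n and the total 2n.
    """
    if query.effect == 0:
        raise ValueError("effect = 0 is infeasible")
    if query.design == "one_sample_t":
        n = _smallest_n(
            lambda n: t_test_power(query.effect, n, query.alpha, query.tails, "one_sample_t"),
            query.power,
            2,
        )
        return {"n_total": n}
    if query.design == "two_sample_t":
        n = _smallest_n(
            lambda n: t_test_power(query.effect, n, query.alpha, query.tails, "two_sample_t"),
            query.power,
            2,
        )
        return {"n_per_group": n, "n_total": 2 * n}
    raise ValueError("use sample_size_correlation for the correlation design")


def sample_size_correlation(query: PowerQuery) -> int:
    """Sample size for detecting a correlation, via the Fisher-z approximation.

    n = ((z_{1-alpha/tails} + z_{power}) / atanh(r))^2 + 3, rounded up.  The
    approximation can differ by about one unit from exact-test tables.
    """
    r = abs(query.effect)
    if not 0 < r < 1:
        raise ValueError("correlation effect must satisfy 0 < |r| < 1")
    z_alpha = stats.norm.ppf(1 - query.alpha / query.tails)
    z_power = stats.norm.ppf(query.power)
    n = ((z_alpha + z_power) / np.arctanh(r)) ** 2 + 3
    return int(np.ceil(n))
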