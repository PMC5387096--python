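"""Aggregated logit models for dyadic sequences (Bakeman-Gottman 4-step approach).

For each dyad, the lag-1 dependence of one partner's behavior on both
partners' previous behaviors is summarized in a 4 x 2 state-transition table
and fitted by a saturated effect-coded logistic model with four parameters:
a grand-mean logit b0, an actor effect (own behavior at t-1), a partner
effect (other's behavior at t-1), and their interaction.  Because the model
is saturated, the coefficients have a closed form in the four row log-odds.
Per-dyad coefficients are then averaged across dyads and tested with
one-sample t statistics; running the procedure for both partners' outcomes
yields an actor-partner interdependence model (APIM).

Zero cells make log-odds infinite; the conservative default adds a constant
of 0.5 to every cell of every table (not only those with zeros), which is
what makes single-dyad results reproducible and slightly shrinks effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqdata import Dataset, DyadSequencePair

# Row order of the transition table: joint prior state (A, B) at t-1.
ROW_ORDER = ((1, 1), (1, 0), (0, 1), (0, 0))
_A_CODE = np.array([1.0, 1.0, -1.0, -1.0])  # effect code of A's prior behavior per row
_B_CODE = np.array([1.0, -1.0, 1.0, -1.0])  # effect code of B's prior behavior per row


class ZeroFrequencyError(ValueError):
    """A table cell is zero and no continuity constant was applied."""


@dataclass
class TransitionTable:
    """4 x 2 counts of (joint prior state at t-1, target behavior at t).

    Rows are ordered (A=yes,B=yes), (A=yes,B=no), (A=no,B=yes), (A=no,B=no);
    columns are (target shown, target not shown).  The counts sum to
    T_obs - 1 transitions.
    """

    target: str  # "A" or "B"
    counts: np.ndarray
    dyad_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (4, 2):
            raise ValueError("counts must be 4 x 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())


@dataclass
class LogitParams:
    """Saturated effect-coded logit coefficients for one dyad."""

    b0: float
    b_actor: float
    b_partner: float
    b_ixn: float
    constant_used: float = 0.0
    dyad_id: str = ""

    def as_array(self) -> np.ndarray:
        return np.array([self.b0, self.b_actor, self.b_partner, self.b_ixn])

    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.as_array())


PARAM_NAMES = ("b0", "b_actor", "b_partner", "b_ixn")


@dataclass
class AggregateLogit:
    """Across-dyad aggregation of per-dyad logit coefficients.

    For each parameter: mean, SD, one-sample t against 0 with df = n - 1,
    two-tailed p, and the odds ratio exp(mean).  ``t`` and ``p`` are NaN when
    the across-dyad SD is zero (degenerate case, flagged).
    """

    target: str
    mean: np.ndarray
    sd: np.ndarray
    t: np.ndarray
    df: int
    p: np.ndarray
    odds_ratio: np.ndarray
    n_dyads: int
    n_excluded: int
    excluded_ids: list[str]
    per_dyad: list[LogitParams]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": PARAM_NAMES,
                "mean": self.mean,
                "sd": self.sd,
                "t": self.t,
                "df": self.df,
                "p": self.p,
                "odds_ratio": self.odds_ratio,
            }
        )


def transition_table(pair: DyadSequencePair, target: str) -> TransitionTable:
    """Count (joint prior state, target behavior) pairs over t = 2..T_obs."""
    if target not in ("A", "B"):
        raise ValueError("target must be 'A' or 'B'")
    outcome = pair.seq_a if target == "A" else pair.seq_b
    counts = np.zeros((4, 2))
    prior = list(zip(pair.seq_a[:-1], pair.seq_b[:-1]))
    row_index = {ab: i for i, ab in enumerate(ROW_ORDER)}
    for (a, b), y in zip(prior, outcome[1:]):
        counts[row_index[(a, b)], 0 if y == 1 else 1] += 1
    return TransitionTable(target=target, counts=counts, dyad_id=pair.dyad_id)


def fit_saturated_logit(table: TransitionTable, constant: float = 0.5) -> LogitParams:
    """Closed-form fit of the saturated effect-coded logit model.

    With row log-odds L_s = ln((n_yes + c) / (n_no + c)) and effect codes
    (+1/-1) for the two prior behaviors, the coefficients are orthogonal
    contrasts: b0 = mean(L), b_actor = sum(own * L)/4, b_partner =
    sum(other * L)/4, b_ixn = sum(own * other * L)/4.  With c = 0 on
    all-positive tables this equals maximum-likelihood logistic regression on
    the grouped data, since the model is saturated.
    """
    if constant < 0:
        raise ValueError("constant must be >= 0")
    c = table.counts + constant
    if (c <= 0).any():
        raise ZeroFrequencyError(
            f"dyad {table.dyad_id or '?'}: zero cell frequency with constant=0; "
            "use constant=0.5 or the 'drop' exclusion policy"
        )
    log_odds = np.log(c[:, 0] / c[:, 1])
    actor_code = _A_CODE if table.target == "A" else _B_CODE
    partner_code = _B_CODE if table.target == "A" else _A_CODE
    return LogitParams(
        b0=float(log_odds.mean()),
        b_actor=float((actor_code * log_odds).mean()),
        b_partner=float((partner_code * log_odds).mean()),
        b_ixn=float((actor_code * partner_code * log_odds).mean()),
        constant_used=constant,
        dyad_id=table.dyad_id,
    )


def _aggregate(params: list[LogitParams], target: str, n_excluded: int, excluded_ids) -> AggregateLogit:
    if len(params) < 2:
        raise ValueError("need at least 2 usable dyads to aggregate")
    mat = np.array([p.as_array() for p in params])
    n = len(params)
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / math.sqrt(n)), np.nan)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    return AggregateLogit(
        target=target,
        mean=mean,
        sd=sd,
        t=t,
        df=n - 1,
        p=p,
        odds_ratio=np.exp(mean),
        n_dyads=n,
        n_excluded=n_excluded,
        excluded_ids=list(excluded_ids),
        per_dyad=params,
    )


def aggregate_logit(
    dataset: Dataset,
    target: str,
    constant: float = 0.5,
    exclusion_policy: str = "correct",
) -> AggregateLogit:
    """Fit the saturated logit per dyad and aggregate across dyads.

    ``exclusion_policy='correct'`` (default) adds ``constant`` to every cell
    of every table; ``'drop'`` excludes dyads whose table contains any zero
    cell and fits the rest with no constant.
    """
    if exclusion_policy not in ("correct", "drop"):
        raise ValueError("exclusion_policy must be 'correct' or 'drop'")
    params: list[LogitParams] = []
    excluded: list[str] = []
    for pair in dataset.pairs:
        table = transition_table(pair, target)
        if exclusion_policy == "drop":
            if (table.counts == 0).any():
                excluded.append(pair.dyad_id)
                continue
            params.append(fit_saturated_logit(table, constant=0.0))
        else:
            params.append(fit_saturated_logit(table, constant=constant))
    return _aggregate(params, target, len(excluded), excluded)


@dataclass
class ApimSummary:
    """Aggregated logits for both outcomes plus paired between-outcome tests."""

    outcome_a: AggregateLogit
    outcome_b: AggregateLogit
    diff_mean: np.ndarray  # outcome A minus outcome B, per parameter
    diff_t: np.ndarray
    diff_df: int
    diff_p: np.ndarray


def apim_summary(
    dataset: Dataset, constant: float = 0.5, exclusion_policy: str = "correct"
) -> ApimSummary:
    """Run the aggregation for both partners' outcomes (the full APIM).

    Also reports per-parameter differences between the two outcomes with
    paired t-tests over the dyads usable for both fits.
    """
    agg_a = aggregate_logit(dataset, "A", constant, exclusion_policy)
    agg_b = aggregate_logit(dataset, "B", constant, exclusion_policy)
    by_id_a = {p.dyad_id: p.as_array() for p in agg_a.per_dyad}
    by_id_b = {p.dyad_id: p.as_array() for p in agg_b.per_dyad}
    common = [i for i in by_id_a if i in by_id_b]
    diffs = np.array([by_id_a[i] - by_id_b[i] for i in common])
    n = len(common)
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / math.sqrt(n)), np.nan)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    return ApimSummary(
        outcome_a=agg_a, outcome_b=agg_b, diff_mean=mean, diff_t=t, diff_df=n - 1, diff_p=p
    )


def compare_logit_groups(
    group1: list[LogitParams], group2: list[LogitParams]
) -> dict[str, dict[str, float]]:
    """Welch two-sample t-test per parameter between two groups of dyads.

    Returns, per parameter, the mean difference (group1 - group2), Welch t,
    Welch-Satterthwaite df and the two-tailed p.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("both groups need at least 2 dyads")
    m1 = np.array([p.as_array() for p in group1])
    m2 = np.array([p.as_array() for p in group2])
    out: dict[str, dict[str, float]] = {}
    for j, name in enumerate(PARAM_NAMES):
        x, y = m1[:, j], m2[:, j]
        delta = float(x.mean() - y.mean())
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            out[name] = {
                "delta": delta,
                "t": np.nan if delta == 0 else np.inf * np.sign(delta),
                "df": np.nan,
                "p": 1.0 if delta == 0 else 0.0,
            }
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        v1, v2 = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        df = (v1 + v2) ** 2 / (v1**2 / (len(x) - 1) + v2**2 / (len(y) - 1))
        out[name] = {"delta": delta, "t": float(t), "df": float(df), "p": float(p)}
    return out
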