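"""Data model, I/O, state expansion and descriptive statistics for dyadic sequences.

A dyad is observed by interval sampling: the observation period is split into
T equal intervals and, for each interval, the occurrence (1) or non-occurrence
(0) of one behavior per partner is coded.  The atomic unit is therefore a pair
of aligned binary streams, e.g. one partner's stress communication and the
other partner's dyadic coping.  The two streams can be joined into a single
sequence over four joint states (none / A-only / B-only / both), which is the
representation used by the Markov-family models and by optimal matching.

Dropout is allowed only as a terminal suffix of missing values: a couple that
leaves the study early contributes a shorter, but still contiguous, record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# Fixed global alphabet for the expanded joint state sequence.
STATE_NONE = 0
STATE_A_ONLY = 1
STATE_B_ONLY = 2
STATE_BOTH = 3
N_STATES = 4
STATE_NAMES = ("NONE", "A_ONLY", "B_ONLY", "BOTH")


class SchemaError(ValueError):
    """Input table does not match the expected wide layout."""


class NonTerminalMissingError(ValueError):
    """Missing values occur inside a sequence rather than as a dropout suffix."""


@dataclass
class DyadSequencePair:
    """Two aligned binary behavior streams for one dyad, plus covariates.

    ``seq_a`` and ``seq_b`` hold 0/1 codes per observation interval; both have
    the same observed length ``T_obs >= 2``.
    """

    dyad_id: str
    seq_a: np.ndarray
    seq_b: np.ndarray
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq_a = np.asarray(self.seq_a, dtype=int)
        self.seq_b = np.asarray(self.seq_b, dtype=int)
        if self.seq_a.ndim != 1 or self.seq_b.ndim != 1:
            raise SchemaError(f"dyad {self.dyad_id}: sequences must be 1-D")
        if len(self.seq_a) != len(self.seq_b):
            raise SchemaError(
                f"dyad {self.dyad_id}: unequal observed lengths "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        if len(self.seq_a) < 2:
            raise ValueError(f"dyad {self.dyad_id}: needs at least 2 observed intervals")
        for name, seq in (("A", self.seq_a), ("B", self.seq_b)):
            bad = ~np.isin(seq, (0, 1))
            if bad.any():
                t = int(np.nonzero(bad)[0][0]) + 1
                raise ValueError(
                    f"dyad {self.dyad_id}: non-binary code in stream {name} at interval {t}"
                )

    @property
    def t_obs(self) -> int:
        return len(self.seq_a)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DyadSequencePair)
            and self.dyad_id == other.dyad_id
            and np.array_equal(self.seq_a, other.seq_a)
            and np.array_equal(self.seq_b, other.seq_b)
            and self.covariates == other.covariates
        )


@dataclass
class StateSequence:
    """Expanded joint 4-state sequence for one dyad.

    Alphabet order is fixed globally as (NONE, A_ONLY, B_ONLY, BOTH) so that
    transition matrices from different model fits are directly comparable.
    """

    dyad_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.ndim != 1:
            raise ValueError("states must be 1-D")
        if ((self.states < 0) | (self.states >= N_STATES)).any():
            raise ValueError(f"dyad {self.dyad_id}: state codes must be in 0..{N_STATES - 1}")

    @property
    def t_obs(self) -> int:
        return len(self.states)


@dataclass
class Dataset:
    """A collection of dyads with display labels for the two behavior streams."""

    pairs: list[DyadSequencePair]
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        ids = [p.dyad_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("dyad_ids must be unique")

    @property
    def n_dyads(self) -> int:
        return len(self.pairs)

    @property
    def t_max(self) -> int:
        return max(p.t_obs for p in self.pairs) if self.pairs else 0

    def state_sequences(self) -> list[StateSequence]:
        return [expand_states(p) for p in self.pairs]


@dataclass
class DescriptiveSummary:
    """Per-interval state distribution, normalized Shannon entropy and per-dyad
    state-transition counts.

    ``state_distribution[s, t]`` is the share of dyads still observed at
    interval ``t`` (0-based internally) that are in joint state ``s``; entropy
    is normalized by ln(4) so it ranges over [0, 1]; ``transition_counts[i]``
    counts the intervals at which dyad ``i`` changed its joint state.
    """

    state_distribution: np.ndarray
    entropy: np.ndarray
    transition_counts: np.ndarray
    n_observed: np.ndarray
    dyad_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Per-interval descriptives as a table with 1-based interval index."""
        t = np.arange(1, self.state_distribution.shape[1] + 1)
        data = {"interval": t, "n_observed": self.n_observed}
        for s, name in enumerate(STATE_NAMES):
            data[f"p_{name}"] = self.state_distribution[s]
        data["entropy"] = self.entropy
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# State expansion

def expand_states(pair: DyadSequencePair) -> StateSequence:
    """Join the two binary streams into one 4-state sequence.

    Element-wise mapping: (a=0,b=0) -> NONE, (1,0) -> A_ONLY, (0,1) -> B_ONLY,
    (1,1) -> BOTH.
    """
    return StateSequence(pair.dyad_id, pair.seq_a + 2 * pair.seq_b)


def collapse_states(states: StateSequence) -> DyadSequencePair:
    """Exact inverse of :func:`expand_states`."""
    s = states.states
    return DyadSequencePair(states.dyad_id, s % 2, s // 2)


# ---------------------------------------------------------------------------
# File I/O


def _sequence_columns(columns, prefix: str | None, explicit: list[str] | None, what: str):
    if explicit is not None:
        missing = [c for c in explicit if c not in columns]
        if missing:
            raise SchemaError(f"{what}: columns not found: {missing}")
        return list(explicit)
    if prefix is None:
        raise SchemaError(f"{what}: give either a prefix or an explicit column list")
    found = [c for c in columns if c.startswith(prefix)]
    if not found:
        raise SchemaError(f"{what}: no columns with prefix {prefix!r}")

    def sort_key(c):
        suffix = c[len(prefix):]
        return (0, int(suffix)) if suffix.isdigit() else (1, suffix)

    return sorted(found, key=sort_key)


def _strip_terminal_nan(values: np.ndarray, dyad_id: str, what: str) -> np.ndarray:
    isna = pd.isna(values)
    if not isna.any():
        return values
    first = int(np.argmax(isna))
    if not isna[first:].all():
        raise NonTerminalMissingError(
            f"dyad {dyad_id}: non-terminal missingness in {what} "
            f"(gap starts at interval {first + 1})"
        )
    return values[:first]


def read_dyads(
    path,
    a_prefix: str | None = None,
    b_prefix: str | None = None,
    a_columns: list[str] | None = None,
    b_columns: list[str] | None = None,
    id_column: str | None = None,
    covariate_columns: list[str] | None = None,
    label_a: str = "A",
    label_b: str = "B",
    sep: str | None = None,
) -> Dataset:
    """Read a wide-format CSV/TSV table with one row per dyad.

    The two behavior streams are identified either by column-name prefix
    (columns sorted by their numeric suffix) or by explicit column lists.
    Terminal missing cells shorten ``T_obs`` (dropout); internal gaps raise
    :class:`NonTerminalMissingError`.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    return dataset_from_frame(
        df,
        a_prefix=a_prefix,
        b_prefix=b_prefix,
        a_columns=a_columns,
        b_columns=b_columns,
        id_column=id_column,
        covariate_columns=covariate_columns,
        label_a=label_a,
        label_b=label_b,
    )


def dataset_from_frame(
    df: pd.DataFrame,
    a_prefix: str | None = None,
    b_prefix: str | None = None,
    a_columns: list[str] | None = None,
    b_columns: list[str] | None = None,
    id_column: str | None = None,
    covariate_columns: list[str] | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> Dataset:
    """Build a validated :class:`Dataset` from a wide-format DataFrame."""
    cols_a = _sequence_columns(df.columns, a_prefix, a_columns, "stream A")
    cols_b = _sequence_columns(df.columns, b_prefix, b_columns, "stream B")
    if len(cols_a) != len(cols_b):
        raise SchemaError(
            f"unequal number of A and B columns ({len(cols_a)} vs {len(cols_b)})"
        )
    if id_column is None:
        id_column = "dyad_id" if "dyad_id" in df.columns else None
    if covariate_columns is None:
        used = set(cols_a) | set(cols_b) | ({id_column} if id_column else set())
        covariate_columns = [c for c in df.columns if c not in used]

    pairs = []
    for i, row in df.iterrows():
        dyad_id = str(row[id_column]) if id_column else str(i)
        a = _strip_terminal_nan(row[cols_a].to_numpy(dtype=float), dyad_id, "stream A")
        b = _strip_terminal_nan(row[cols_b].to_numpy(dtype=float), dyad_id, "stream B")
        if len(a) != len(b):
            raise SchemaError(
                f"dyad {dyad_id}: dropout lengths differ between streams "
                f"({len(a)} vs {len(b)})"
            )
        cov = {c: float(row[c]) for c in covariate_columns if not pd.isna(row[c])}
        pairs.append(DyadSequencePair(dyad_id, a.astype(int), b.astype(int), cov))
    return Dataset(pairs, label_a=label_a, label_b=label_b)


def write_dyads(dataset: Dataset, path, sep: str = ",") -> None:
    """Write a dataset in the standard wide format (dropouts as trailing NA)."""
    t_max = dataset.t_max
    rows = []
    cov_names = sorted({k for p in dataset.pairs for k in p.covariates})
    for p in dataset.pairs:
        row: dict = {"dyad_id": p.dyad_id}
        for t in range(t_max):
            row[f"a_{t + 1}"] = p.seq_a[t] if t < p.t_obs else np.nan
        for t in range(t_max):
            row[f"b_{t + 1}"] = p.seq_b[t] if t < p.t_obs else np.nan
        for k in cov_names:
            row[k] = p.covariates.get(k, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Descriptive statistics


def describe(dataset: Dataset) -> DescriptiveSummary:
    """Per-interval state distribution, normalized entropy and transition counts.

    With dropouts the per-interval denominator is the number of dyads still
    under observation at that interval.
    """
    if dataset.n_dyads == 0:
        raise ValueError("empty dataset")
    t_max = dataset.t_max
    counts = np.zeros((N_STATES, t_max))
    n_observed = np.zeros(t_max, dtype=int)
    transition_counts = np.zeros(dataset.n_dyads, dtype=int)
    for i, seq in enumerate(dataset.state_sequences()):
        s = seq.states
        n_observed[: len(s)] += 1
        counts[s, np.arange(len(s))] += 1
        transition_counts[i] = int(np.count_nonzero(np.diff(s)))
    dist = counts / n_observed
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(dist > 0, dist * np.log(dist), 0.0)
    entropy = -plogp.sum(axis=0) / math.log(N_STATES)
    return DescriptiveSummary(
        state_distribution=dist,
        entropy=np.clip(entropy, 0.0, 1.0),
        transition_counts=transition_counts,
        n_observed=n_observed,
        dyad_ids=[p.dyad_id for p in dataset.pairs],
    )


def behavior_frequencies(dataset: Dataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-dyad counts of 1-intervals in each behavior stream."""
    freq_a = np.array([int(p.seq_a.sum()) for p in dataset.pairs])
    freq_b = np.array([int(p.seq_b.sum()) for p in dataset.pairs])
    return freq_a, freq_b


def frequency_correlation(dataset: Dataset) -> tuple[float, float]:
    """Pearson correlation between the per-dyad behavior frequencies.

    Answers the most aggregate question — do dyads in which partner A shows
    the behavior often also see partner B respond often?  Frequencies are raw
    counts of 1-intervals; with unequal observed lengths (dropouts) a warning
    is emitted because counts are then not comparable across dyads.
    """
    if dataset.n_dyads < 3:
        raise ValueError("need at least 3 dyads for a correlation")
    lengths = {p.t_obs for p in dataset.pairs}
    if len(lengths) > 1:
        import warnings

        warnings.warn(
            "observed lengths differ across dyads; raw frequency counts are "
            "not directly comparable",
            stacklevel=2,
        )
    freq_a, freq_b = behavior_frequencies(dataset)
    if np.ptp(freq_a) == 0 or np.ptp(freq_b) == 0:
        raise ValueError("zero variance in a frequency vector; correlation undefined")
    r, p = stats.pearsonr(freq_a, freq_b)
    return float(r), float(p)
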