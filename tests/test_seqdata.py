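"""Data model, I/O, state expansion and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyadseq as dq
from dyadseq.seqdata import (
    N_STATES,
    NonTerminalMissingError,
    SchemaError,
    behavior_frequencies,
)


class TestDyadSequencePair:
    def test_valid_pair(self):
        p = dq.DyadSequencePair("x", [0, 1, 1], [1, 0, 1])
        assert p.t_obs == 3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(SchemaError, match="unequal"):
            dq.DyadSequencePair("x", [0, 1], [1, 0, 1])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            dq.DyadSequencePair("x", [1], [0])

    def test_non_binary_rejected_with_position(self):
        with pytest.raises(ValueError, match="stream B at interval 3"):
            dq.DyadSequencePair("x", [0, 1, 1], [1, 0, 2])

    def test_duplicate_ids_rejected(self):
        p = dq.DyadSequencePair("x", [0, 1], [1, 0])
        q = dq.DyadSequencePair("x", [1, 1], [0, 0])
        with pytest.raises(ValueError, match="unique"):
            dq.Dataset([p, q])


class TestStateExpansion:
    def test_mapping(self):
        p = dq.DyadSequencePair("x", [0, 1, 0, 1], [0, 0, 1, 1])
        s = dq.expand_states(p)
        assert s.states.tolist() == [0, 1, 2, 3]

    def test_collapse_inverts(self):
        p = dq.DyadSequencePair("x", [0, 1, 1, 0, 1], [1, 1, 0, 0, 1])
        assert dq.collapse_states(dq.expand_states(p)) == p

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40))
    def test_roundtrip_property(self, states):
        s = dq.StateSequence("x", np.array(states))
        back = dq.expand_states(dq.collapse_states(s))
        assert np.array_equal(back.states, s.states)

    def test_invalid_state_code(self):
        with pytest.raises(ValueError, match="state codes"):
            dq.StateSequence("x", [0, 4])


class TestIO:
    def test_write_read_roundtrip(self, small_dataset, tmp_path):
        path = tmp_path / "d.csv"
        dq.write_dyads(small_dataset, path)
        back = dq.read_dyads(path, a_prefix="a_", b_prefix="b_")
        assert back.n_dyads == small_dataset.n_dyads
        for orig, new in zip(small_dataset.pairs, back.pairs):
            assert new == orig

    def test_roundtrip_with_dropout(self, tmp_path):
        pairs = [
            dq.DyadSequencePair("1", [1, 0, 1, 1], [0, 1, 1, 0]),
            dq.DyadSequencePair("2", [1, 0], [0, 1]),  # dropped out after t=2
        ]
        path = tmp_path / "d.csv"
        dq.write_dyads(dq.Dataset(pairs), path)
        back = dq.read_dyads(path, a_prefix="a_", b_prefix="b_")
        assert [p.t_obs for p in back.pairs] == [4, 2]
        assert back.pairs[1].seq_a.tolist() == [1, 0]

    def test_tsv_separator_inferred(self, small_dataset, tmp_path):
        path = tmp_path / "d.tsv"
        dq.write_dyads(small_dataset, path, sep="\t")
        back = dq.read_dyads(path, a_prefix="a_", b_prefix="b_")
        assert back.n_dyads == small_dataset.n_dyads

    def test_non_terminal_gap_rejected(self, tmp_path):
        df = pd.DataFrame(
            {
                "a_1": [1.0],
                "a_2": [np.nan],
                "a_3": [1.0],
                "b_1": [0.0],
                "b_2": [1.0],
                "b_3": [0.0],
            }
        )
        with pytest.raises(NonTerminalMissingError, match="interval 2"):
            dq.dataset_from_frame(df, a_prefix="a_", b_prefix="b_")

    def test_mismatched_dropout_lengths_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"a_1": [1.0], "a_2": [np.nan], "b_1": [0.0], "b_2": [1.0]}
        )
        with pytest.raises(SchemaError, match="dropout lengths differ"):
            dq.dataset_from_frame(df, a_prefix="a_", b_prefix="b_")

    def test_missing_prefix_rejected(self):
        df = pd.DataFrame({"x_1": [1], "x_2": [0]})
        with pytest.raises(SchemaError, match="prefix"):
            dq.dataset_from_frame(df, a_prefix="a_", b_prefix="b_")

    def test_numeric_suffix_sorting(self):
        # a_10 must sort after a_2, not between a_1 and a_2
        cols = {}
        for t in range(1, 12):
            cols[f"a_{t}"] = [t % 2]
            cols[f"b_{t}"] = [0 if t < 11 else 1]
        df = pd.DataFrame(cols)
        ds = dq.dataset_from_frame(df, a_prefix="a_", b_prefix="b_")
        assert ds.pairs[0].seq_a.tolist() == [t % 2 for t in range(1, 12)]
        assert ds.pairs[0].seq_b.tolist() == [0] * 10 + [1]

    def test_explicit_columns_and_covariates(self):
        df = pd.DataFrame(
            {
                "dyad_id": ["d9"],
                "u1": [1],
                "u2": [0],
                "v1": [0],
                "v2": [1],
                "age": [33.0],
            }
        )
        ds = dq.dataset_from_frame(df, a_columns=["u1", "u2"], b_columns=["v1", "v2"])
        assert ds.pairs[0].dyad_id == "d9"
        assert ds.pairs[0].covariates == {"age": 33.0}


class TestDescribe:
    def test_distribution_columns_sum_to_one(self, markov_dataset):
        summary = dq.describe(markov_dataset)
        np.testing.assert_allclose(summary.state_distribution.sum(axis=0), 1.0)

    def test_known_small_case(self):
        # two dyads: interval 1 has states BOTH and NONE, interval 2 both A_ONLY
        pairs = [
            dq.DyadSequencePair("1", [1, 1], [1, 0]),
            dq.DyadSequencePair("2", [0, 1], [0, 0]),
        ]
        summary = dq.describe(dq.Dataset(pairs))
        np.testing.assert_allclose(
            summary.state_distribution[:, 0], [0.5, 0, 0, 0.5]
        )
        np.testing.assert_allclose(summary.state_distribution[:, 1], [0, 1, 0, 0])
        # entropy: two equiprobable states of 4 -> ln2/ln4 = 0.5; then 0
        np.testing.assert_allclose(summary.entropy, [0.5, 0.0])
        assert summary.transition_counts.tolist() == [1, 1]

    def test_dropout_denominator(self):
        pairs = [
            dq.DyadSequencePair("1", [1, 1, 1], [1, 1, 1]),
            dq.DyadSequencePair("2", [0, 0], [0, 0]),
        ]
        summary = dq.describe(dq.Dataset(pairs))
        assert summary.n_observed.tolist() == [2, 2, 1]
        # at t=3 only dyad 1 remains, in state BOTH
        np.testing.assert_allclose(summary.state_distribution[:, 2], [0, 0, 0, 1])

    def test_to_frame_shape(self, small_dataset):
        frame = dq.describe(small_dataset).to_frame()
        assert list(frame["interval"]) == [1, 2, 3, 4, 5, 6]
        assert {"p_NONE", "p_A_ONLY", "p_B_ONLY", "p_BOTH", "entropy"} <= set(
            frame.columns
        )

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_entropy_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [
            dq.DyadSequencePair(str(i), rng.integers(0, 2, 6), rng.integers(0, 2, 6))
            for i in range(4)
        ]
        summary = dq.describe(dq.Dataset(pairs))
        assert (summary.entropy >= 0).all() and (summary.entropy <= 1).all()


class TestFrequencies:
    def test_counts(self, small_dataset):
        fa, fb = behavior_frequencies(small_dataset)
        assert fa.tolist() == [3, 3, 6, 1, 3, 4]
        assert fb.tolist() == [3, 3, 5, 1, 3, 4]

    def test_correlation_matches_numpy(self, small_dataset):
        r, p = dq.frequency_correlation(small_dataset)
        fa, fb = behavior_frequencies(small_dataset)
        np.testing.assert_allclose(r, np.corrcoef(fa, fb)[0, 1])
        assert 0 <= p <= 1

    def test_unequal_lengths_warn(self):
        pairs = [
            dq.DyadSequencePair("1", [1, 0, 1], [0, 1, 1]),
            dq.DyadSequencePair("2", [0, 1], [1, 0]),
            dq.DyadSequencePair("3", [1, 1, 1], [0, 0, 1]),
        ]
        with pytest.warns(UserWarning, match="not directly comparable"):
            dq.frequency_correlation(dq.Dataset(pairs))

    def test_zero_variance_rejected(self):
        pairs = [
            dq.DyadSequencePair(str(i), [1, 0], [i % 2, 1]) for i in range(4)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            dq.frequency_correlation(dq.Dataset(pairs))
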