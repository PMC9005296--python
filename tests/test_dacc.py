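import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhkit import (
    DaccConfig,
    DnaSequence,
    LabeledDataset,
    PropertyTable,
    dac,
    dacc_matrix,
    dacc_vector,
    dcc,
    property_mean,
)
from enhkit.sequence_io import DINUCLEOTIDES, SequenceError


def covariance_oracle(seq, name1, name2, lag, table):
    """Independent brute-force double loop over 1-based positions."""
    r = seq.residues
    length = len(r)
    p1 = [table.value(name1, r[i : i + 2]) for i in range(length - 1)]
    p2 = [table.value(name2, r[i : i + 2]) for i in range(length - 1)]
    m1 = sum(p1) / len(p1)
    m2 = sum(p2) / len(p2)
    total = 0.0
    for i in range(1, length - lag):  # i = 1 .. L - lag - 1
        total += (p1[i - 1] - m1) * (p2[i - 1 + lag] - m2)
    return total / (length - lag - 1)


class TestWorkedExample:
    """The printed 8-bp example: sequence TACATTCA under Shift and Slide."""

    def test_property_means(self, worked_sequence, shift_slide_table):
        assert property_mean(worked_sequence, "Shift", shift_slide_table) == pytest.approx(-0.449, abs=5e-4)
        assert property_mean(worked_sequence, "Slide", shift_slide_table) == pytest.approx(0.109, abs=5e-4)

    def test_dac_at_lag_five(self, worked_sequence, shift_slide_table):
        value = dac(worked_sequence, "Shift", 5, shift_slide_table)
        assert value == pytest.approx(-0.634, abs=5e-4)

    def test_dcc_at_lag_five(self, worked_sequence, shift_slide_table):
        # the printed 0.241 is derived from 3-decimal rounded means
        # (-0.449, 0.109); the full-precision value is 0.240478
        value = dcc(worked_sequence, "Shift", "Slide", 5, shift_slide_table)
        assert value == pytest.approx(0.241, abs=1e-3)
        shift = [-2.243, 0.126]  # P_Shift(TA), P_Shift(AC)
        lagged = [-0.394, -0.623]  # P_Slide(TC), P_Slide(CA)
        rounded = sum((a + 0.449) * (b - 0.109) for a, b in zip(shift, lagged)) / 2
        assert rounded == pytest.approx(0.241, abs=5e-4)

    def test_full_precision_against_oracle(self, worked_sequence, shift_slide_table):
        assert dac(worked_sequence, "Shift", 5, shift_slide_table) == pytest.approx(
            covariance_oracle(worked_sequence, "Shift", "Shift", 5, shift_slide_table),
            abs=1e-15,
        )

    def test_duplicate_dinucleotides_count_with_multiplicity(self, worked_sequence, shift_slide_table):
        # CA occurs twice in TACATTCA; dropping the repeat would give a
        # visibly different mean (~0.198 instead of ~0.109 for Slide)
        assert property_mean(worked_sequence, "Slide", shift_slide_table) != pytest.approx(0.198, abs=5e-3)


class TestScalarOperations:
    def test_homopolymer_mean_is_the_single_value(self, random_table):
        table = random_table(1, seed=1)
        seq = DnaSequence("homo", "AAAA")
        assert property_mean(seq, "prop000", table) == pytest.approx(
            table.value("prop000", "AA")
        )

    def test_homopolymer_dac_is_zero(self, random_table):
        table = random_table(1, seed=2)
        assert dac(DnaSequence("h", "AAAAAAAA"), "prop000", 1, table) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(20))
    def test_dac_dcc_match_brute_force(self, seed, random_table, random_sequence):
        rng = np.random.default_rng(1000 + seed)
        table = random_table(3, seed=seed)
        seq = random_sequence(int(rng.integers(10, 40)), seed=seed)
        lag = int(rng.integers(1, len(seq) - 2))
        a, b = rng.choice(table.names, 2, replace=False)
        assert dac(seq, a, lag, table) == pytest.approx(
            covariance_oracle(seq, a, a, lag, table), abs=1e-12
        )
        assert dcc(seq, a, b, lag, table) == pytest.approx(
            covariance_oracle(seq, a, b, lag, table), abs=1e-12
        )

    def test_dcc_with_equal_properties_reduces_to_dac(self, random_table, random_sequence):
        table = random_table(2, seed=3)
        seq = random_sequence(25, seed=3)
        for lag in (1, 3, 7):
            assert dcc(seq, "prop000", "prop000", lag, table) == pytest.approx(
                dac(seq, "prop000", lag, table), abs=1e-15
            )

    def test_dcc_order_matters(self, random_table, random_sequence):
        table = random_table(2, seed=4)
        seq = random_sequence(30, seed=4)
        ab = dcc(seq, "prop000", "prop001", 2, table)
        ba = dcc(seq, "prop001", "prop000", 2, table)
        assert ab != pytest.approx(ba, abs=1e-9)

    def test_lag_too_large_names_minimum_length(self, random_table):
        with pytest.raises(SequenceError, match="minimum length is 7"):
            dac(DnaSequence("s", "ACGTAC"), "prop000", 5, random_table(1))


class TestCovarianceInvariants:
    @settings(max_examples=30, deadline=None)
    @given(
        shift=st.floats(-5, 5, allow_nan=False),
        scale=st.floats(0.5, 3, allow_nan=False),
        seed=st.integers(0, 100),
    )
    def test_shift_invariance_and_scale_covariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(2, 16))
        base = PropertyTable(("a", "b"), values)
        moved = PropertyTable(("a", "b"), np.vstack([values[0] + shift, values[1]]))
        scaled = PropertyTable(("a", "b"), np.vstack([values[0] * scale, values[1]]))
        seq = DnaSequence("s", "".join(rng.choice(list("ACGT"), size=20)))
        lag = int(rng.integers(1, 10))
        assert dac(seq, "a", lag, moved) == pytest.approx(dac(seq, "a", lag, base), rel=1e-9, abs=1e-12)
        assert dcc(seq, "a", "b", lag, moved) == pytest.approx(dcc(seq, "a", "b", lag, base), rel=1e-9, abs=1e-12)
        assert dac(seq, "a", lag, scaled) == pytest.approx(scale**2 * dac(seq, "a", lag, base), rel=1e-9, abs=1e-12)
        assert dcc(seq, "a", "b", lag, scaled) == pytest.approx(scale * dcc(seq, "a", "b", lag, base), rel=1e-9, abs=1e-12)


class TestVectorLayout:
    def test_canonical_dimension_47_properties(self, random_table, random_sequence):
        table = random_table(47, seed=9)
        config = DaccConfig(table.names, lag=5)
        assert config.dimension == 11045
        vec = dacc_vector(random_sequence(200, seed=9), config, table)
        assert len(vec.values) == 11045
        assert len(set(vec.labels)) == 11045

    @pytest.mark.parametrize("n,lag", [(1, 1), (1, 4), (2, 2), (3, 5), (5, 3)])
    def test_dimension_identity(self, n, lag, random_table, random_sequence):
        table = random_table(n, seed=n)
        vec = dacc_vector(random_sequence(40, seed=lag), DaccConfig(table.names, lag), table)
        assert len(vec.values) == n * n * lag

    def test_single_property_has_empty_dcc_block(self, random_table, random_sequence):
        table = random_table(1, seed=5)
        vec = dacc_vector(random_sequence(10, seed=5), DaccConfig(table.names, 1), table)
        assert len(vec.values) == 1
        assert vec.labels == ("DAC|prop000|1",)

    def test_two_property_layout_matches_per_call_values(self, random_table, random_sequence):
        table = random_table(2, seed=6)
        a, b = table.names
        seq = random_sequence(30, seed=6)
        vec = dacc_vector(seq, DaccConfig(table.names, 2), table)
        expected_labels = (
            f"DAC|{a}|1", f"DAC|{a}|2", f"DAC|{b}|1", f"DAC|{b}|2",
            f"DCC|{a}|{b}|1", f"DCC|{a}|{b}|2", f"DCC|{b}|{a}|1", f"DCC|{b}|{a}|2",
        )
        assert vec.labels == expected_labels
        expected_values = [
            dac(seq, a, 1, table), dac(seq, a, 2, table),
            dac(seq, b, 1, table), dac(seq, b, 2, table),
            dcc(seq, a, b, 1, table), dcc(seq, a, b, 2, table),
            dcc(seq, b, a, 1, table), dcc(seq, b, a, 2, table),
        ]
        np.testing.assert_allclose(vec.values, expected_values, atol=1e-14)


class TestFeatureMatrix:
    def test_rows_equal_per_sequence_vectors(self, random_table, random_sequence):
        table = random_table(2, seed=7)
        config = DaccConfig(table.names, 3)
        seqs = [random_sequence(25, seed=s, ident=f"s{s}") for s in range(4)]
        ds = LabeledDataset(seqs, ["non_enhancer"] * 4)
        matrix = dacc_matrix(ds, config, table)
        assert matrix.shape == (4, config.dimension)
        assert list(matrix.index) == [s.id for s in seqs]
        for seq in seqs:
            np.testing.assert_allclose(
                matrix.loc[seq.id].to_numpy(),
                dacc_vector(seq, config, table).values,
                atol=1e-14,
            )

    def test_empty_dataset_keeps_labels(self, random_table):
        table = random_table(2, seed=8)
        config = DaccConfig(table.names, 2)
        matrix = dacc_matrix(LabeledDataset([], []), config, table)
        assert matrix.shape == (0, config.dimension)

    def test_failures_collected_with_sequence_ids(self, random_table, random_sequence):
        table = random_table(1, seed=9)
        config = DaccConfig(table.names, 5)
        ds = LabeledDataset(
            [random_sequence(20, ident="ok"), DnaSequence("short1", "ACGT"),
             DnaSequence("short2", "ACGTA")],
            [""] * 3,
        )
        with pytest.raises(SequenceError, match="short1(.|\n)*short2"):
            dacc_matrix(ds, config, table)
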