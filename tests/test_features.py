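import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morfmlp import ConfigurationError, SequenceRecord, WindowConfig
from morfmlp.features import (
    PAD_LETTER,
    entropy_subword_params,
    pad,
    pool_to_residues,
    property_features,
    profile_features,
    topological_entropy,
    window_entropy_values,
    window_means,
    window_scale_values,
)
from morfmlp.seq_io import ALPHABET, PSSMProfile, ScaleTable

from conftest import random_record


def constant_scale(c: float) -> ScaleTable:
    return ScaleTable("const", {a: c for a in ALPHABET})


def brute_force_residue_features(values, length, n):
    """Independent oracle: direct average of covering-window averages.

    Pads with zeros, enumerates every window explicitly, and for residue j
    averages the means of the windows containing padded position j+n0.
    """
    n0 = n // 2
    padded = [0.0] * n0 + list(values) + [0.0] * n0
    window_avgs = [sum(padded[i : i + n]) / n for i in range(len(padded) - n + 1)]
    out = []
    for j in range(1, length + 1):
        pos = j + n0  # 1-based padded position of residue j
        covering = [window_avgs[i - 1] for i in range(1, len(window_avgs) + 1)
                    if i <= pos <= i + n - 1]
        out.append(sum(covering) / len(covering))
    return out


class TestPad:
    def test_length_l3_n10(self):
        assert len(pad(np.ones(3), 10)) == 13

    def test_length_l5_n45(self):
        assert len(pad(np.ones(5), 45)) == 49

    def test_pads_are_exact_zero(self):
        padded = pad(np.array([1.5, 2.5]), 8)
        assert (padded[:4] == 0.0).all() and (padded[-4:] == 0.0).all()

    def test_letter_padding(self):
        assert pad("MKV", 4, PAD_LETTER) == "--MKV--"


class TestWindowScaleValues:
    def test_interior_window_of_constant_scale(self):
        record = SequenceRecord("s", "A" * 30)
        v = window_scale_values(record, constant_scale(2.0), 10)
        # fully interior windows: indices n0..n0+L-N
        assert v[10] == pytest.approx(2.0)

    def test_half_padded_window(self):
        record = SequenceRecord("s", "A" * 30)
        n = 10
        v = window_scale_values(record, constant_scale(3.0), n)
        # first window covers n0=5 pads and 5 residues
        assert v[0] == pytest.approx(3.0 * 5 / n)

    def test_matches_brute_force_window_means(self, rng):
        record = random_record(rng, 8)
        scale = ScaleTable("rand", {a: float(rng.normal()) for a in ALPHABET})
        n = 4
        v = window_scale_values(record, scale, n)
        padded = [0.0] * 2 + [scale.value(a) for a in record.residues] + [0.0] * 2
        expected = [sum(padded[i : i + n]) / n for i in range(len(padded) - n + 1)]
        np.testing.assert_allclose(v, expected, atol=1e-13)


class TestTopologicalEntropy:
    def test_constant_window_is_zero(self):
        assert topological_entropy("A" * 10) == 0.0

    def test_all_distinct_letters_is_one(self):
        assert topological_entropy(ALPHABET) == pytest.approx(1.0)

    def test_subword_params(self):
        assert entropy_subword_params(10, 20) == (1, 10)
        assert entropy_subword_params(45, 20) == (1, 20)
        assert entropy_subword_params(5, 2) == (2, 5)  # 2^2+1=5 <= 5

    def test_small_alphabet_n2(self):
        # A=2, window "ABABB": n=2, m=5, distinct 2-mers {AB, BA, BB} -> log2(3)/2
        assert topological_entropy("ABABB", 2) == pytest.approx(math.log2(3) / 2)

    def test_random_window_matches_brute_force(self, rng):
        record = random_record(rng, 45)
        value = window_entropy_values(record, 45)[22]  # a fully interior window
        window = record.residues[0:45]
        n, m = 1, 20
        distinct = {window[i : i + n] for i in range(m - n + 1)}
        assert value == pytest.approx(math.log(len(distinct), 20) / n)

    def test_pad_counts_as_distinct_symbol(self):
        record = SequenceRecord("s", "A" * 10)
        v = window_entropy_values(record, 10)
        # first window "-----AAAAA": 2 distinct symbols, not 1
        assert v[0] == pytest.approx(math.log(2, 20))
        # interior windows of a homopolymer are zero-complexity
        assert v[len(v) // 2] == 0.0

    @given(st.integers(1, 40), st.integers(2, 12), st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_entropy_range(self, length, n, seed):
        record = random_record(np.random.default_rng(seed), length)
        values = window_entropy_values(record, n)
        n_sub, m = entropy_subword_params(n, 20)
        upper = math.log(m - n_sub + 1, 20) / n_sub
        assert (values >= 0).all()
        assert (values <= upper + 1e-12).all()


class TestPoolToResidues:
    def test_constant_windows(self):
        x = pool_to_residues(np.full(21, 3.25), 20, 10)
        np.testing.assert_allclose(x, 3.25)

    def test_interior_residue_uses_exactly_n_windows(self):
        # one-hot window values make the contributing count readable
        length, n = 30, 10
        n0 = n // 2
        n_windows = length + 2 * n0 - n + 1
        j = 15  # interior: n0 < j <= length - n0
        total = 0.0
        for i in range(n_windows):
            v = np.zeros(n_windows)
            v[i] = 1.0
            total += pool_to_residues(v, length, n)[j - 1]
        # sum over one-hots of the pooled value equals (#covering windows)/count = 1
        assert total == pytest.approx(1.0)
        v = np.ones(n_windows)
        contributing = [i for i in range(1, n_windows + 1)
                        if i <= j + n0 <= i + n - 1]
        assert len(contributing) == n

    def test_l3_n2_first_residue(self, worked):
        case = worked["pooling"]
        x = pool_to_residues(np.array(case["v"]), case["length"], case["n"])
        assert x[0] == pytest.approx((case["v"][0] + case["v"][1]) / 2)
        np.testing.assert_allclose(x, case["expected"], atol=1e-14)

    def test_wrong_window_count_rejected(self):
        with pytest.raises(ConfigurationError):
            pool_to_residues(np.ones(5), 20, 10)

    @given(st.integers(1, 30), st.integers(2, 12), st.integers(0, 2**31))
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence(self, length, n, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=length)
        pooled = pool_to_residues(window_means(pad(values, n), n), length, n)
        expected = brute_force_residue_features(values, length, n)
        np.testing.assert_allclose(pooled, expected, atol=1e-12)


class TestPropertyFeatures:
    def test_default_dimension_is_48(self, scales, rng):
        fm = property_features(random_record(rng, 120), scales)
        assert fm.values.shape == (120, 48)
        assert fm.branch == "properties"
        assert len(fm.column_names) == 48

    def test_single_window_dimension_is_16(self, scales, rng):
        fm = property_features(random_record(rng, 40), scales,
                               WindowConfig(sizes=(10,)))
        assert fm.values.shape == (40, 16)
        assert fm.column_names[0] == "entropy@10"

    def test_determinism(self, scales, rng):
        record = random_record(rng, 50)
        a = property_features(record, scales)
        b = property_features(record, scales)
        np.testing.assert_array_equal(a.values, b.values)

    def test_wrong_scale_count_rejected(self, scales, rng):
        with pytest.raises(ConfigurationError, match="15"):
            property_features(random_record(rng, 30), scales[:10])

    def test_column_order_entropy_first_then_file_order(self, scales, rng):
        fm = property_features(random_record(rng, 30), scales)
        names = fm.column_names
        assert names[0] == "entropy@10"
        assert names[1] == f"{scales[0].name}@10"
        assert names[16] == "entropy@45"
        assert names[32] == "entropy@90"

    def test_short_sequence_processed_with_warning(self, scales, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="morfmlp.features"):
            fm = property_features(SequenceRecord("s", "MKV"), scales)
        assert fm.values.shape == (3, 48)
        assert np.isfinite(fm.values).all()
        assert any("window size" in r.message for r in caplog.records)

    def test_length_one_sequence_is_finite(self, scales):
        fm = property_features(SequenceRecord("s", "M"), scales)
        assert np.isfinite(fm.values).all()

    @given(st.integers(0, 2**31), st.integers(1, 8))
    @settings(max_examples=15, deadline=None)
    def test_translation_equivariance(self, seed, k):
        rng = np.random.default_rng(seed)
        scale = ScaleTable("rand", {a: float(rng.normal()) for a in ALPHABET})
        n = 6
        base = random_record(rng, 60)
        prefix = "".join(rng.choice(list(ALPHABET), size=k))
        shifted = SequenceRecord("s2", prefix + base.residues)
        n0 = n // 2
        x_base = pool_to_residues(window_means(pad(scale.vector(base.residues), n), n),
                                  len(base), n)
        x_shift = pool_to_residues(
            window_means(pad(scale.vector(shifted.residues), n), n), len(shifted), n)
        margin = n0 + n
        interior = slice(margin, len(base) - margin)
        np.testing.assert_allclose(x_shift[k:][interior], x_base[interior], atol=1e-12)


class TestProfileFeatures:
    def test_all_zero_pssm(self, rng):
        record = random_record(rng, 50)
        pssm = PSSMProfile(record.id, np.zeros((20, 50)), record.residues)
        fm = profile_features(record, pssm)
        assert fm.values.shape == (50, 60)
        assert (fm.values == 0).all()

    def test_default_dimension_is_60(self, tiny_dataset):
        record = tiny_dataset.records[0]
        fm = profile_features(record, tiny_dataset.profiles[record.id])
        assert fm.values.shape == (len(record), 60)
        assert fm.branch == "profile"

    def test_constant_pssm_interior_residues(self, rng):
        record = random_record(rng, 60)
        c = 4.0
        pssm = PSSMProfile(record.id, np.full((20, 60), c), record.residues)
        fm = profile_features(record, pssm, WindowConfig(sizes=(11,)))
        n0 = 5
        interior = fm.values[2 * n0 + 11 : 60 - 2 * n0 - 11]
        np.testing.assert_allclose(interior, c, atol=1e-12)

    def test_misaligned_pssm_rejected(self, rng):
        from morfmlp import AlignmentError

        record = random_record(rng, 30)
        other = random_record(np.random.default_rng(999), 30)
        pssm = PSSMProfile("other", np.zeros((20, 30)), other.residues)
        with pytest.raises(AlignmentError):
            profile_features(record, pssm)
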