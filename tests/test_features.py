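from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protclass import (
    FeatureMatrix,
    FeatureScheme,
    ProteinRecord,
    aac_scheme,
    compute_aac,
    compute_dpc,
    compute_pseaac,
    correlation_factor,
    dpc_scheme,
    featurize_dataset,
    normalize_property,
    pseaac_scheme,
    theta,
)
from protclass.features import DIPEPTIDES
from protclass.sequence_io import ALPHABET

from conftest import random_records

canonical_seq = st.text(alphabet=ALPHABET, min_size=1, max_size=100)


class TestAAC:
    def test_homopolymer_is_pure(self):
        vec = compute_aac("AAAAA")
        assert vec[ALPHABET.index("A")] == 100.0
        assert vec.sum() == 100.0

    def test_equal_mixture(self):
        vec = compute_aac("ACDE")
        for ch in "ACDE":
            assert vec[ALPHABET.index(ch)] == 25.0
        assert np.count_nonzero(vec) == 4

    def test_matches_letter_counting_oracle(self, rng):
        seq = random_records(rng, 1, 200, 200)[0].sequence
        counts = Counter(seq)
        expected = np.array([100 * counts.get(ch, 0) / 200 for ch in ALPHABET])
        np.testing.assert_allclose(compute_aac(seq), expected)

    @given(seq=canonical_seq)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sums_to_100_and_shuffle_invariant(self, seq):
        vec = compute_aac(seq)
        assert vec.sum() == pytest.approx(100.0)
        shuffled = "".join(sorted(seq))
        np.testing.assert_allclose(compute_aac(shuffled), vec)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_aac("")


class TestDPC:
    def test_single_dipeptide(self):
        vec = compute_dpc("AAA", "fraction")
        assert vec[DIPEPTIDES.index("AA")] == 1.0
        assert vec.sum() == 1.0

    def test_alternating_windows_counted_by_hand(self):
        # ACAC has windows AC, CA, AC
        vec = compute_dpc("ACAC", "fraction")
        assert vec[DIPEPTIDES.index("AC")] == pytest.approx(2 / 3)
        assert vec[DIPEPTIDES.index("CA")] == pytest.approx(1 / 3)

    def test_per400_sum_is_forced_by_definition(self, rng):
        seq = random_records(rng, 1, 11, 11)[0].sequence
        assert compute_dpc(seq, "per400").sum() == pytest.approx(10 / 400)

    @given(seq=st.text(alphabet=ALPHABET, min_size=2, max_size=100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fraction_mode_sums_to_one(self, seq):
        assert compute_dpc(seq, "fraction").sum() == pytest.approx(1.0)

    def test_order_sensitivity_witness(self):
        # same residue multiset, different order, same AAC, different DPC
        a, b = "AACC", "ACAC"
        np.testing.assert_allclose(compute_aac(a), compute_aac(b))
        assert not np.allclose(compute_dpc(a), compute_dpc(b))

    def test_too_short_and_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            compute_dpc("A")
        with pytest.raises(ValueError):
            compute_dpc("AC", mode="per100")


class TestProperties:
    def test_normalization_gives_zero_mean_unit_sd(self):
        out = normalize_property(np.arange(1.0, 21.0))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0, abs=1e-12)

    def test_normalization_is_idempotent(self):
        once = normalize_property(np.arange(1.0, 21.0))
        np.testing.assert_allclose(normalize_property(once), once, atol=1e-12)

    def test_all_equal_values_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            normalize_property(np.full(20, 3.14))

    def test_shipped_hydrophobicity_normalized_by_hand_for_A(self, props):
        raw = props.hydrophobicity
        expected = (raw[0] - raw.mean()) / raw.std()
        assert props.normalized[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_theta_zero_on_diagonal_and_symmetric(self, props):
        assert theta("A", "A", props) == 0.0
        for r1 in ALPHABET:
            for r2 in ALPHABET:
                assert theta(r1, r2, props) == pytest.approx(theta(r2, r1, props))

    def test_theta_hand_computed_for_A_C(self, props):
        diffs = props.normalized[:, ALPHABET.index("C")] - props.normalized[:, ALPHABET.index("A")]
        expected = float((diffs**2).sum() / 3)
        assert theta("A", "C", props) == pytest.approx(expected)

    def test_unknown_residue_rejected(self, props):
        with pytest.raises(ValueError):
            theta("A", "B", props)


class TestCorrelationFactor:
    def test_homopolymer_always_zero(self, props):
        for k in (1, 2, 5):
            assert correlation_factor("AAAAAA", k, props) == 0.0

    def test_alternating_sequence_zero_at_even_lag(self, props):
        assert correlation_factor("ACACAC", 2, props) == 0.0

    def test_matches_direct_summation(self, props):
        seq = "ACDEFG"
        expected = np.mean([theta(seq[i], seq[i + 1], props) for i in range(5)])
        assert correlation_factor(seq, 1, props) == pytest.approx(expected)

    def test_lag_bounds_enforced(self, props):
        with pytest.raises(ValueError):
            correlation_factor("ACDE", 4, props)


class TestPseAAC:
    def test_dimension_is_20_plus_lambda(self, props):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert compute_pseaac(seq, lam=5, props=props).shape == (25,)

    def test_lambda_zero_reduces_to_aac_fractions(self, props, rng):
        seq = random_records(rng, 1, 50, 50)[0].sequence
        np.testing.assert_allclose(
            compute_pseaac(seq, lam=0, props=props), compute_aac(seq) / 100
        )

    def test_homopolymer_correlation_terms_vanish(self, props):
        vec = compute_pseaac("A" * 30, lam=3, props=props)
        np.testing.assert_allclose(vec[20:], 0.0)
        np.testing.assert_allclose(vec[:20], compute_aac("A" * 30) / 100)

    def test_matches_brute_force_formula(self, props, rng):
        seq = random_records(rng, 1, 100, 100)[0].sequence
        lam, w = 5, 0.05
        f = np.array([seq.count(ch) / len(seq) for ch in ALPHABET])
        t = np.array(
            [
                np.mean([theta(seq[i], seq[i + k], props) for i in range(len(seq) - k)])
                for k in range(1, lam + 1)
            ]
        )
        denom = f.sum() + w * t.sum()
        expected = np.concatenate([f, w * t]) / denom
        got = compute_pseaac(seq, lam=lam, w=w, props=props)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-9)

    @given(seq=st.text(alphabet=ALPHABET, min_size=8, max_size=80))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_sums_to_one(self, props, seq):
        assert compute_pseaac(seq, lam=5, props=props).sum() == pytest.approx(1.0)

    def test_sequence_shorter_than_lambda_rejected(self, props):
        with pytest.raises(ValueError, match="lambda"):
            compute_pseaac("ACD", lam=5, props=props)


class TestSchemesAndMatrices:
    @pytest.mark.parametrize(
        "scheme,dim",
        [(aac_scheme(), 20), (dpc_scheme(), 400), (pseaac_scheme(lam=5), 25)],
    )
    def test_featurize_dimensions(self, toy_dataset, scheme, dim):
        fm = featurize_dataset(toy_dataset, scheme)
        assert fm.values.shape == (6, dim)
        assert fm.labels.tolist() == toy_dataset.labels.tolist()
        assert fm.feature_names == scheme.feature_names

    def test_failing_record_is_named(self, toy_dataset):
        with pytest.raises(ValueError, match="P1"):
            featurize_dataset(toy_dataset, pseaac_scheme(lam=15))

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            FeatureScheme("CTD")
        with pytest.raises(ValueError):
            FeatureScheme("PseAAC", lam=3, w=0)
        with pytest.raises(ValueError):
            FeatureScheme("DPC", dpc_mode="weird")

    def test_csv_round_trip(self, toy_dataset, tmp_path):
        fm = featurize_dataset(toy_dataset, aac_scheme())
        path = tmp_path / "fm.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.ids == fm.ids
        assert back.scheme.name == "AAC"
        np.testing.assert_allclose(back.values, fm.values)
        assert back.labels.tolist() == fm.labels.tolist()

    def test_duplicate_row_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            FeatureMatrix(["a", "a"], np.zeros((2, 20)), aac_scheme())
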