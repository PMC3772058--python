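import numpy as np
import pandas as pd
import pytest

from _oracles import oracle_auc
from timma.core import predict_state
from timma.scoring import (
    EfficacyMatrix,
    enumerate_efficacy_matrix,
    rank_synthetic_lethal_partners,
    roc_sensitive_drugs,
    synergy_drug_pair,
    synergy_table,
    synergy_target_pair,
    synthetic_lethality_score,
)


def matrix_from(values, targets=("A", "B")):
    return EfficacyMatrix(targets=tuple(targets), values=values)


class TestEfficacyMatrix:
    def test_full_mode_state_count(self, chain):
        X, y = chain
        M = enumerate_efficacy_matrix(X[:, :2], y, targets=("A", "B"))
        assert len(M.values) == 4

    def test_pairwise_mode_states(self):
        X = np.eye(4, dtype=np.int8)
        y = np.array([0.2, 0.4, 0.6, 0.8])
        M = enumerate_efficacy_matrix(X, y, mode="pairwise")
        assert len(M.values) == 1 + 4 + 6
        assert all(bin(m).count("1") <= 2 for m in M.values)

    def test_training_profile_state_returns_its_efficacy(self, chain):
        X, y = chain
        M = enumerate_efficacy_matrix(X, y, targets=("A", "B", "C"))
        assert M.efficacy(["A", "B"]) == 0.6
        assert M.efficacy(["A", "B", "C"]) == 0.9

    def test_matches_rule_engine_on_chain(self, chain):
        X, y = chain
        M = enumerate_efficacy_matrix(X, y, targets=("A", "B", "C"))
        for mask, value in M.values.items():
            state = np.array([(mask >> b) & 1 for b in range(3)], dtype=np.int8)
            expected = predict_state(X, y, state).value
            if np.isnan(expected):
                assert np.isnan(value)
            else:
                assert value == pytest.approx(expected)

    def test_pairwise_frame_is_symmetric(self, chain):
        X, y = chain
        M = enumerate_efficacy_matrix(X, y, targets=("A", "B", "C"))
        F = M.to_pairwise_frame()
        assert F.equals(F.T)


class TestSynergy:
    def test_zero_singles_passes_pair_efficacy_through(self):
        # matches the published top drug-pair rows where both single
        # efficacies are zero and the pair efficacy 0.723 is the synergy
        M = matrix_from({0: 0.0, 1: 0.0, 2: 0.0, 3: 0.723})
        assert synergy_target_pair(M, "A", "B") == pytest.approx(0.723)
        assert synergy_target_pair(M, "A", "B", null="product") == pytest.approx(0.723)

    def test_null_expectation_scores_zero(self):
        y_a, y_b = 0.3, 0.4
        bliss = y_a + y_b - y_a * y_b
        M = matrix_from({0: 0.0, 1: y_a, 2: y_b, 3: bliss})
        assert synergy_target_pair(M, "A", "B") == pytest.approx(0.0)

    def test_two_nulls_diverge_as_expected(self):
        M = matrix_from({0: 0.0, 1: 0.3, 2: 0.4, 3: 0.58})
        assert synergy_target_pair(M, "A", "B") == pytest.approx(0.0)
        assert synergy_target_pair(M, "A", "B", null="product") == pytest.approx(0.46)

    def test_symmetry(self):
        M = matrix_from({0: 0.0, 1: 0.5, 2: 0.2, 3: 0.9})
        assert synergy_target_pair(M, "A", "B") == synergy_target_pair(M, "B", "A")

    def test_non_identifiable_gives_nan(self):
        M = matrix_from({0: 0.0, 1: 0.5, 2: 0.2, 3: float("nan")})
        assert np.isnan(synergy_target_pair(M, "A", "B"))

    def test_drug_pair_mean_and_degenerate_cases(self):
        values = {0: 0.0}
        targets = ("a", "b", "c")
        # singles
        values[1], values[2], values[4] = 0.0, 0.0, 0.0
        values[1 | 2] = 0.2  # a,b
        values[1 | 4] = 0.4  # a,c
        values[2 | 4] = 0.1  # b,c
        M = EfficacyMatrix(targets=targets, values=values)
        assert synergy_drug_pair(M, ["a"], ["b"]) == pytest.approx(0.2)
        assert synergy_drug_pair(M, ["a"], ["b", "c"]) == pytest.approx(0.3)
        assert np.isnan(synergy_drug_pair(M, ["a"], ["a"]))  # identical drugs

    def test_synergy_table_layout(self, chain):
        X, y = chain
        M = enumerate_efficacy_matrix(X, y, targets=("A", "B", "C"))
        table = synergy_table(M)
        assert len(table) == 3
        assert set(table.columns) >= {"target_a", "target_b", "synergy"}


class TestSyntheticLethality:
    def test_perfect_and_gives_infinity(self):
        X = np.array(
            [[1, 1], [1, 0], [0, 1], [0, 0], [1, 1]], dtype=np.int8
        )
        y = np.array([1.0, 0.0, 0.0, 0.0, 1.0])
        s = synthetic_lethality_score(X, y, 0, 1)
        assert s.tss_parallel == 0.0
        assert s.score == np.inf

    def test_perfect_or_gives_zero(self):
        X = np.array(
            [[1, 1], [1, 0], [0, 1], [0, 0], [0, 0]], dtype=np.int8
        )
        y = np.array([1.0, 1.0, 1.0, 0.0, 0.0])
        s = synthetic_lethality_score(X, y, 0, 1)
        assert s.tss_series == 0.0
        assert s.score == 0.0

    def test_noisy_and_pattern_hand_computed(self):
        X = np.array(
            [
                [1, 1], [1, 1], [1, 0], [1, 0],
                [0, 1], [0, 1], [0, 0], [0, 0],
            ],
            dtype=np.int8,
        )
        y = np.array([0.9, 1.0, 0.1, 0.2, 0.15, 0.05, 0.0, 0.1])
        s = synthetic_lethality_score(X, y, 0, 1)
        # hand-computed pooled within-group sums of squares
        group = lambda v: float(((np.asarray(v) - np.mean(v)) ** 2).sum())
        tss_par = group([0.9, 1.0]) + group([0.1, 0.2, 0.15, 0.05, 0.0, 0.1])
        tss_ser = group([0.9, 1.0, 0.1, 0.2, 0.15, 0.05]) + group([0.0, 0.1])
        tss_a = group([0.9, 1.0, 0.1, 0.2]) + group([0.15, 0.05, 0.0, 0.1])
        tss_b = group([0.9, 1.0, 0.15, 0.05]) + group([0.1, 0.2, 0.0, 0.1])
        assert s.tss_parallel == pytest.approx(tss_par)
        assert s.tss_series == pytest.approx(tss_ser)
        assert s.tss_singleton == pytest.approx(min(tss_a, tss_b))
        assert s.score == pytest.approx(min(tss_ser, min(tss_a, tss_b)) / tss_par)
        assert s.score > 1.0

    def test_swap_invariance(self, random_instance):
        for seed in range(30):
            X, y, _ = random_instance(seed, n_min=6, m_min=2)
            a, b = 0, X.shape[1] - 1
            s1 = synthetic_lethality_score(X, y, a, b)
            s2 = synthetic_lethality_score(X, y, b, a)
            assert (np.isnan(s1.score) and np.isnan(s2.score)) or (
                s1.score == pytest.approx(s2.score)
            )

    def test_empty_group_gives_na_with_reason(self):
        X = np.array([[1, 1], [1, 1], [0, 1]], dtype=np.int8)
        y = np.array([0.5, 0.6, 0.1])
        s = synthetic_lethality_score(X, y, 0, 1)  # no state 00
        assert np.isnan(s.score)
        assert s.reason


class TestRankPartners:
    def test_perfect_and_partner_above_baseline(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(30, 4)).astype(np.int8)
        y = (X[:, 0] & X[:, 1]).astype(float)
        X = pd.DataFrame(X, columns=["anchor", "partner", "n1", "n2"])
        ranked = rank_synthetic_lethal_partners(X, y, "anchor")
        assert "partner" in ranked["target"].tolist()
        assert ranked.iloc[0]["target"] == "partner"

    def test_all_targets_identical_to_anchor_yield_empty(self):
        col = np.array([1, 0, 1, 0, 1], dtype=np.int8)
        X = pd.DataFrame({"anchor": col, "t1": col, "t2": col})
        y = np.array([0.9, 0.1, 0.8, 0.2, 0.7])
        ranked = rank_synthetic_lethal_partners(X, y, "anchor")
        assert len(ranked) == 0

    def test_tied_targets_share_rank(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 2, size=(40, 2)).astype(np.int8)
        X = pd.DataFrame(
            {
                "anchor": base[:, 0],
                "p1": base[:, 1],
                "p2": base[:, 1],  # same drug set -> same score
            }
        )
        y = (base[:, 0] & base[:, 1]).astype(float)
        ranked = rank_synthetic_lethal_partners(X, y, "anchor")
        assert set(ranked["target"]) == {"p1", "p2"}
        assert ranked["rank"].tolist() == [1, 1]


class TestRoc:
    def test_perfect_separation(self):
        _, _, _, auc = roc_sensitive_drugs([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_constant_predictions_give_half(self):
        _, _, _, auc = roc_sensitive_drugs([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=20)
        labels = rng.integers(0, 2, size=20)
        if len(np.unique(labels)) < 2:
            labels[0] = 1 - labels[0]
        _, _, _, auc = roc_sensitive_drugs(scores, labels)
        assert auc == pytest.approx(oracle_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_sensitive_drugs([0.1, 0.2], [1, 1])
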