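"""Soft voting, splits, ROC/AUC from first principles, base learners."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genecoord import (
    EnsembleConfig,
    SplitSpec,
    SyntheticConfig,
    accuracy,
    auc,
    evaluate_ensemble,
    generate_dataset,
    predict_labels,
    roc_curve,
    soft_vote,
    train_test_split,
)
from genecoord.ensemble import GaussianClassConditional, LeastSquaresScorer


def _prob_frame(p_ad, samples=None):
    p_ad = np.asarray(p_ad, dtype=float)
    samples = samples or [f"s{i}" for i in range(p_ad.size)]
    return pd.DataFrame({"CON": 1 - p_ad, "AD": p_ad}, index=samples)


def _auc_pair_counting(scores, labels):
    """Mann-Whitney oracle: fraction of (pos, neg) pairs won, ties half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


class TestTrainTestSplit:
    def test_sizes_80_20(self):
        y = np.array(["AD"] * 50 + ["CON"] * 50)
        train, test = train_test_split(y, SplitSpec(train_fraction=0.8, seed=1))
        assert train.size == 80 and test.size == 20
        assert set(train) | set(test) == set(range(100))
        assert set(train) & set(test) == set()

    def test_stratification_within_one_sample(self):
        y = np.array(["AD"] * 60 + ["CON"] * 40)
        train, _ = train_test_split(y, SplitSpec(train_fraction=0.8, seed=2, stratified=True))
        n_ad = (y[train] == "AD").sum()
        assert abs(n_ad - 48) <= 1

    def test_same_seed_same_split(self):
        y = np.array(["AD", "CON"] * 30)
        s = SplitSpec(train_fraction=0.8, seed=3)
        assert np.array_equal(train_test_split(y, s)[0], train_test_split(y, s)[0])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            SplitSpec(train_fraction=1.0)


class TestSoftVote:
    def test_weighted_hand_arithmetic(self):
        probs = {
            "RF": _prob_frame([0.9]),
            "SVM": _prob_frame([0.8]),
            "GMM": _prob_frame([0.2]),
            "LM": _prob_frame([0.4]),
        }
        out = soft_vote(probs)  # default weights 2/2/1/1
        assert out["AD"].iloc[0] == pytest.approx((1.8 + 1.6 + 0.2 + 0.4) / 6, abs=1e-12)

    def test_identical_models_are_fixed_point(self):
        p = _prob_frame([0.3, 0.7, 0.5])
        out = soft_vote({m: p.copy() for m in ["RF", "SVM", "GMM", "LM"]})
        assert np.allclose(out.to_numpy(), p.to_numpy(), atol=1e-12)

    def test_equal_weights_is_plain_mean(self):
        probs = {
            "RF": _prob_frame([0.9, 0.1]),
            "SVM": _prob_frame([0.5, 0.3]),
            "GMM": _prob_frame([0.1, 0.5]),
            "LM": _prob_frame([0.5, 0.1]),
        }
        cfg = EnsembleConfig(weights={m: 1.0 for m in probs})
        out = soft_vote(probs, cfg)
        stack = np.stack([p["AD"].to_numpy() for p in probs.values()])
        assert np.allclose(out["AD"].to_numpy(), stack.mean(axis=0), atol=1e-12)

    @given(c=st.floats(min_value=0.01, max_value=100))
    def test_weight_rescaling_invariance(self, c):
        probs = {
            "RF": _prob_frame([0.9, 0.2]),
            "SVM": _prob_frame([0.8, 0.6]),
            "GMM": _prob_frame([0.2, 0.4]),
            "LM": _prob_frame([0.4, 0.5]),
        }
        base = {"RF": 2.0, "SVM": 2.0, "GMM": 1.0, "LM": 1.0}
        a = soft_vote(probs, EnsembleConfig(weights=base))
        b = soft_vote(probs, EnsembleConfig(weights={k: c * w for k, w in base.items()}))
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_missing_model_rejected(self):
        probs = {"RF": _prob_frame([0.5]), "SVM": _prob_frame([0.5])}
        with pytest.raises(ValueError, match="missing"):
            soft_vote(probs)

    def test_sample_mismatch_rejected(self):
        probs = {
            "RF": _prob_frame([0.5, 0.5]),
            "SVM": _prob_frame([0.5, 0.5], samples=["x", "y"]),
            "GMM": _prob_frame([0.5, 0.5]),
            "LM": _prob_frame([0.5, 0.5]),
        }
        with pytest.raises(ValueError, match="different samples"):
            soft_vote(probs)

    def test_rows_must_sum_to_one(self):
        bad = pd.DataFrame({"CON": [0.5], "AD": [0.6]}, index=["s0"])
        probs = {m: (bad if m == "GMM" else _prob_frame([0.5])) for m in
                 ["RF", "SVM", "GMM", "LM"]}
        with pytest.raises(ValueError, match="sum to 1"):
            soft_vote(probs)


class TestPredictLabels:
    def test_above_threshold_positive(self):
        labels = predict_labels(_prob_frame([0.6667]), positive_class="AD")
        assert labels.iloc[0] == "AD"

    def test_exact_tie_goes_negative(self):
        labels = predict_labels(_prob_frame([0.5]), positive_class="AD")
        assert labels.iloc[0] == "CON"

    def test_zero_probability_negative(self):
        labels = predict_labels(_prob_frame([0.0]), positive_class="AD")
        assert labels.iloc[0] == "CON"


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.4, 0.2]
        labels = [1, 1, 0, 0]
        fpr, tpr, _ = roc_curve(scores, labels)
        assert (0.0, 1.0) in zip(fpr, tpr)
        assert auc(scores, labels) == pytest.approx(1.0, abs=1e-12)

    def test_all_scores_equal_gives_diagonal(self):
        fpr, tpr, _ = roc_curve([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert np.allclose(fpr, [0, 1]) and np.allclose(tpr, [0, 1])
        assert auc([0.5] * 4, [1, 0, 1, 0]) == pytest.approx(0.5, abs=1e-12)

    def test_pair_enumeration_example(self):
        # pairs: 0.9>0.4 yes, 0.9>0.8 yes, 0.2>0.4 no, 0.2>0.8 no -> 0.5
        assert auc([0.9, 0.4, 0.8, 0.2], [1, 0, 0, 1]) == pytest.approx(0.5, abs=1e-12)

    def test_staircase_monotone_and_anchored(self):
        rng = np.random.default_rng(41)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        fpr, tpr, _ = roc_curve(scores, labels)
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_trapezoid_equals_pair_counting_on_random_draws(self):
        rng = np.random.default_rng(43)
        for _ in range(1000):
            n = rng.integers(4, 25)
            # discretized scores so ties actually occur
            scores = np.round(rng.uniform(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc(scores, labels) == pytest.approx(
                _auc_pair_counting(scores, labels), abs=1e-10
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([0.1, 0.2], [1, 1])

    def test_agreement_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(47)
        scores = rng.uniform(size=200)
        labels = rng.integers(0, 2, size=200)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestAccuracy:
    def test_all_correct(self):
        assert accuracy(["AD", "CON"], ["AD", "CON"]) == 1.0

    def test_fraction(self):
        pred = ["AD"] * 78 + ["CON"] * 22
        true = ["AD"] * 100
        assert accuracy(pred, true) == pytest.approx(0.78)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            accuracy(["AD"], ["AD", "CON"])


class TestBaseLearners:
    def test_gaussian_class_conditional_separates_blobs(self):
        rng = np.random.default_rng(53)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(4, 1, (40, 3))])
        y = np.array(["CON"] * 40 + ["AD"] * 40)
        model = GaussianClassConditional().fit(X, y)
        p = model.predict_proba(np.array([[4.0, 4.0, 4.0], [0.0, 0.0, 0.0]]))
        ad_col = list(model.classes_).index("AD")
        assert p[0, ad_col] > 0.95 and p[1, ad_col] < 0.05
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_least_squares_scorer_probabilities_valid(self):
        rng = np.random.default_rng(59)
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(3, 1, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        p = LeastSquaresScorer().fit(X, y).predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestEvaluateEnsemble:
    def test_high_auc_on_shifted_hub_genes(self):
        """Three informative genes, 2-SD shift: ensemble separates groups."""
        cfg = SyntheticConfig(
            gene_modules=(("hubs", ("LCK", "ZAP70", "CD44")),),
            rho_per_group={"AD": {"hubs": 0.4}, "CON": {"hubs": 0.4}},
            group_sizes={"AD": 100, "CON": 100},
            mean_shift={"LCK": 2.0, "ZAP70": 2.0, "CD44": 2.0},
            shift_group="AD",
            seed=61,
        )
        X = generate_dataset(cfg)
        result = evaluate_ensemble(
            X.data.T, X.groups, positive_class="AD", spec=SplitSpec(seed=61)
        )
        assert result["auc"] > 0.9
        assert result["accuracy"] > 0.8

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(
            gene_modules=(("hubs", ("A", "B", "C")),),
            rho_per_group={},
            group_sizes={"AD": 40, "CON": 40},
            mean_shift={"A": 1.5},
            shift_group="AD",
            seed=67,
        )
        X = generate_dataset(cfg)
        r1 = evaluate_ensemble(X.data.T, X.groups, "AD", spec=SplitSpec(seed=5))
        r2 = evaluate_ensemble(X.data.T, X.groups, "AD", spec=SplitSpec(seed=5))
        assert r1["auc"] == r2["auc"]
        assert np.array_equal(
            r1["ensemble_probs"].to_numpy(), r2["ensemble_probs"].to_numpy()
        )
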