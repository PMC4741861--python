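import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from lncgo.centroid_model import (
    CentroidClassifier,
    ModelError,
    crossval_auc,
    decision_score,
    delta_d,
    load_term_model,
    predict_lncrnas,
    roc_auc,
    save_term_model,
    train_term_model,
    youden_cutoff,
)
from lncgo.go_prep import GoldStandard
from lncgo.io_normalize import SignalMatrix
from lncgo.synth import make_class_profiles
from oracles import brute_delta_d, brute_youden, pair_count_auc


def clf(pos, neg, cutoff=None):
    pos = np.asarray(pos, float)
    return CentroidClassifier(
        feature_label="H3K9ac",
        sample_ids=[f"c{i}" for i in range(len(pos))],
        pos_centroid=pos,
        neg_centroid=np.asarray(neg, float),
        cutoff=cutoff,
    )


def _profile_matrix(label, df):
    """Direct profile-space matrix (no normalization-state constraints)."""
    return SignalMatrix(feature_label=label, data=df, state="profile")


class TestDeltaD:
    def test_three_four_five_triangle(self):
        c = clf([0.0, 0.0], [3.0, 4.0])
        assert delta_d([0.0, 0.0], c) == pytest.approx(-5.0)

    def test_equidistant_profile_scores_zero(self):
        c = clf([1.0, 0.0], [-1.0, 0.0])
        assert delta_d([0.0, 5.0], c) == pytest.approx(0.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(20):
            p, a, b = rng.normal(size=(3, 5))
            assert delta_d(p, clf(a, b)) == pytest.approx(
                brute_delta_d(p, a, b), abs=1e-12
            )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ModelError):
            delta_d([1.0, 2.0, 3.0], clf([0.0, 0.0], [1.0, 1.0]))


class TestDecisionScore:
    def test_sign_flip_makes_positive_like_high(self):
        c = clf([0.0, 0.0], [3.0, 4.0])
        assert decision_score([0.0, 0.0], c) == pytest.approx(5.0)

    def test_at_cutoff_is_positive(self):
        c = clf([0.0, 0.0], [3.0, 4.0], cutoff=5.0)
        assert decision_score([0.0, 0.0], c) >= c.cutoff


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([4, 3, 2, 1], [1, 1, 0, 0]) == 1.0

    def test_ties_count_half(self):
        assert roc_auc([1, 1], [1, 0]) == 0.5

    def test_random_instances_match_pair_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            scores = rng.integers(0, 5, size=n).astype(float)  # force ties
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=12),
        st.data(),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_pair_counting_property(self, scores, data):
        n = len(scores)
        n_pos = data.draw(st.integers(1, n - 1))
        labels = [1] * n_pos + [0] * (n - n_pos)
        assert roc_auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), abs=1e-12
        )

    @given(
        st.lists(
            st.integers(-1000, 1000).map(lambda x: x / 100), min_size=4, max_size=12
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, scores):
        # hundredth-grid scores stay distinct under the exp transform
        labels = [1, 0] + [i % 2 for i in range(len(scores) - 2)]
        a = roc_auc(scores, labels)
        b = roc_auc([np.exp(s / 5) for s in scores], labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            roc_auc([1, 2], [1, 1])


class TestYoudenCutoff:
    def test_separated_classes_pick_lowest_positive(self):
        assert youden_cutoff([2, 3, 0, 1], [1, 1, 0, 0]) == 2.0

    def test_degenerate_overlapping_scores_follow_tie_rule(self):
        # all thresholds give J=0; specificity then the lower value decide
        assert youden_cutoff([5, 5, 5, 5], [1, 1, 0, 0]) == 5.0
        assert youden_cutoff([2, 2, 7, 7], [0, 1, 0, 1]) == 7.0
        assert youden_cutoff([2, 2, 7, 7], [0, 1, 0, 1]) == brute_youden(
            [2, 2, 7, 7], [0, 1, 0, 1]
        )

    def test_random_instances_match_enumeration(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 14))
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = np.zeros(n, dtype=int)
            labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            assert youden_cutoff(scores, labels) == brute_youden(scores, labels)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            youden_cutoff([1, 2], [0, 0])


class TestCrossvalAuc:
    def test_null_distribution_centers_on_half(self, rng):
        aucs = [
            crossval_auc(
                rng.normal(size=(50, 10)), rng.normal(size=(50, 10)), seed=s
            )
            for s in range(30)
        ]
        assert 0.45 < np.mean(aucs) < 0.55

    def test_separated_classes_score_high(self):
        aucs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            pos, neg, _ = make_class_profiles(50, 50, 10, 3.0, rng=rng)
            aucs.append(crossval_auc(pos, neg, seed=s))
        assert min(aucs) > 0.95

    def test_same_seed_reproduces(self, rng):
        pos, neg = rng.normal(size=(30, 8)), rng.normal(size=(30, 8))
        assert crossval_auc(pos, neg, seed=4) == crossval_auc(pos, neg, seed=4)

    def test_small_class_rejected(self, rng):
        with pytest.raises(ModelError):
            crossval_auc(rng.normal(size=(4, 8)), rng.normal(size=(30, 8)))

    def test_mean_mode_close_to_pooled(self, rng):
        pos, neg, _ = make_class_profiles(40, 40, 8, 2.0, rng=rng)
        pooled = crossval_auc(pos, neg, seed=1, cv_auc="pooled")
        mean = crossval_auc(pos, neg, seed=1, cv_auc="mean")
        assert abs(pooled - mean) < 0.1


def make_gold_and_matrices(rng, signal_feature="H3K9ac", n_features=4,
                           delta=3.0, n=20, dim=8, n_gsn=10,
                           feature_names=None):
    """Planted-signal setup in direct profile space."""
    genes = [f"P{i}" for i in range(n)]
    backgrounds = [f"B{i}" for i in range(5 * n)]
    gold = GoldStandard(
        term_id="GO:TEST",
        gsp=genes,
        gsn_replicates=[
            [backgrounds[(r * n + i) % len(backgrounds)] for i in range(n)]
            for r in range(n_gsn)
        ],
        rng_seed=0,
    )
    names = feature_names or [f"F{k}" for k in range(n_features)]
    if signal_feature not in names:
        names[0] = signal_feature
    matrices = {}
    centroid = np.zeros(dim)
    centroid[0] = delta
    for name in names:
        rows = rng.normal(size=(n + 5 * n, dim))
        if name == signal_feature:
            rows[:n] += centroid
        matrices[name] = _profile_matrix(
            name,
            pd.DataFrame(rows, index=genes + backgrounds,
                         columns=[f"c{j}" for j in range(dim)]),
        )
    return gold, matrices, centroid


class TestTrainTermModel:
    def test_planted_feature_selected(self, rng):
        gold, matrices, _ = make_gold_and_matrices(rng)
        model = train_term_model(gold, matrices, seed=0)
        assert model.selected_feature == "H3K9ac"
        assert model.auc_by_feature["H3K9ac"] > 0.9
        assert model.n_gsn == gold.n_gsn
        assert all(c.cutoff is not None for c in model.final_classifiers)

    def test_identical_features_tie_break_lexicographic(self, rng):
        gold, matrices, _ = make_gold_and_matrices(
            rng, signal_feature="H3K9ac", n_features=2,
            feature_names=["H3K9ac", "AAA_copy"])
        matrices["AAA_copy"] = _profile_matrix("AAA_copy", matrices["H3K9ac"].data.copy())
        model = train_term_model(gold, matrices, seed=0)
        assert model.selected_feature == "AAA_copy"

    def test_feature_with_missing_gsp_gene_skipped(self, rng):
        gold, matrices, _ = make_gold_and_matrices(rng)
        holed = matrices["F1"].data.drop(index=gold.gsp[0])
        matrices["F1"] = _profile_matrix("F1", holed)
        model = train_term_model(gold, matrices, seed=0, strictness="strict")
        assert "F1" in model.skipped_features
        assert "F1" not in model.auc_by_feature

    def test_lenient_mode_restricts_to_covered(self, rng):
        gold, matrices, _ = make_gold_and_matrices(rng, n=30)
        holed = matrices["H3K9ac"].data.drop(index=gold.gsp[0])
        matrices = {"H3K9ac": _profile_matrix("H3K9ac", holed)}
        model = train_term_model(gold, matrices, seed=0, strictness="lenient")
        assert model.selected_feature == "H3K9ac"

    def test_no_usable_feature_rejected(self, rng):
        gold, matrices, _ = make_gold_and_matrices(rng, n_features=1)
        only = list(matrices)[0]
        holed = matrices[only].data.drop(index=gold.gsp[0])
        with pytest.raises(ModelError, match="no feature"):
            train_term_model(gold, {only: _profile_matrix(only, holed)}, seed=0)

    def test_store_roundtrip(self, rng, tmp_path):
        gold, matrices, _ = make_gold_and_matrices(rng)
        model = train_term_model(gold, matrices, seed=0)
        save_term_model(model, tmp_path / "m")
        back = load_term_model(tmp_path / "m")
        assert back.selected_feature == model.selected_feature
        assert back.auc_by_feature == pytest.approx(model.auc_by_feature)
        for a, b in zip(back.final_classifiers, model.final_classifiers):
            assert a.cutoff == pytest.approx(b.cutoff)
            assert a.pos_centroid == pytest.approx(b.pos_centroid)


class TestPredictLncrnas:
    def test_confidence_on_replicate_grid(self, rng):
        gold, matrices, centroid = make_gold_and_matrices(rng, delta=1.0)
        model = train_term_model(gold, matrices, seed=0)
        lnc = _profile_matrix(
            model.selected_feature,
            pd.DataFrame(rng.normal(size=(10, 8)) + centroid / 2,
                         index=[f"L{i}" for i in range(10)],
                         columns=[f"c{j}" for j in range(8)]),
        )
        recs = predict_lncrnas(model, lnc)
        grid = {i / model.n_gsn for i in range(model.n_gsn + 1)}
        assert all(r.confidence in grid for r in recs)

    def test_centroid_lncrna_full_confidence_far_negative_zero(self, rng):
        gold, matrices, centroid = make_gold_and_matrices(rng, delta=4.0)
        model = train_term_model(gold, matrices, seed=0)
        lnc = _profile_matrix(
            model.selected_feature,
            pd.DataFrame(np.stack([centroid, -10 * centroid]),
                         index=["L_at_centroid", "L_far_negative"],
                         columns=[f"c{j}" for j in range(8)]),
        )
        recs = {r.lncrna_id: r.confidence for r in predict_lncrnas(model, lnc)}
        assert recs["L_at_centroid"] == 1.0
        assert "L_far_negative" not in recs  # confidence 0 -> no record

    def test_feature_mismatch_rejected(self, rng):
        gold, matrices, _ = make_gold_and_matrices(rng)
        model = train_term_model(gold, matrices, seed=0)
        other = matrices[[f for f in matrices if f != model.selected_feature][0]]
        with pytest.raises(ModelError, match="matrix"):
            predict_lncrnas(model, other)

    def test_sample_mismatch_rejected(self, rng):
        gold, matrices, _ = make_gold_and_matrices(rng)
        model = train_term_model(gold, matrices, seed=0)
        lnc = _profile_matrix(
            model.selected_feature,
            pd.DataFrame(rng.normal(size=(2, 8)), index=["L1", "L2"],
                         columns=[f"x{j}" for j in range(8)]),
        )
        with pytest.raises(ModelError, match="sample"):
            predict_lncrnas(model, lnc)
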