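import numpy as np
import pandas as pd
import pytest
from conftest import da, unit_weights
from sklearn.model_selection import StratifiedKFold

from daac import (
    AnnotationSet,
    ScoringParams,
    DomainArchitecture,
    DomainArchitectureGoClassifier,
    GoClass,
    build_classes,
    load_model,
    mean_similarity,
    optimize_threshold,
    predict,
    save_model,
    threshold_grid,
    train,
)


def _annset(pairs):
    return AnnotationSet(
        records=frozenset((p, t, "IDA") for p, t in pairs), propagated=True
    )


class TestBuildClasses:
    def test_term_with_enough_members(self):
        das = {p: da("A", pid=p) for p in ("P1", "P2", "P3")}
        classes = build_classes(_annset([("P1", "t"), ("P2", "t"), ("P3", "t")]),
                                das, min_members=2)
        assert len(classes) == 1 and classes[0].members == {"P1", "P2", "P3"}

    def test_small_term_yields_no_class(self):
        das = {"P1": da("A", pid="P1")}
        assert build_classes(_annset([("P1", "t")]), das, min_members=2) == []

    def test_protein_without_da_not_a_member(self):
        das = {"P1": da("A", pid="P1"), "P2": da("A", pid="P2")}
        classes = build_classes(
            _annset([("P1", "t"), ("P2", "t"), ("P3", "t")]), das, min_members=2)
        assert classes[0].members == {"P1", "P2"}


class TestMeanSimilarity:
    def _sims(self):
        ids = ["Q", "M1", "M2", "M3"]
        m = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        m.loc["Q", ["M1", "M2", "M3"]] = [1.0, 0.5, 0.0]
        m.loc[["M1", "M2", "M3"], "Q"] = [1.0, 0.5, 0.0]
        return m

    def test_arithmetic_mean(self):
        cls = GoClass("t", frozenset({"M1", "M2", "M3"}))
        assert mean_similarity("Q", cls, self._sims()) == pytest.approx(0.5)

    def test_self_excluded_single_member_skipped(self):
        cls = GoClass("t", frozenset({"Q"}))
        assert mean_similarity("Q", cls, self._sims()) is None

    def test_identical_to_all_members(self):
        cls = GoClass("t", frozenset({"M1"}))
        sims = self._sims()
        assert mean_similarity("Q", cls, sims) == pytest.approx(1.0)


def _separable_toy():
    """Six proteins: three mutually identical positives, three negatives
    with zero similarity to the positives."""
    ids = [f"P{i}" for i in range(1, 7)]
    m = np.zeros((6, 6))
    m[:3, :3] = 1.0
    m[3:, 3:] = np.eye(3)
    np.fill_diagonal(m, 1.0)
    sims = pd.DataFrame(m, index=ids, columns=ids)
    cls = GoClass("t", frozenset({"P1", "P2", "P3"}))
    return cls, sims, ids


class TestOptimizeThreshold:
    def test_separable_toy_selects_highest_tied_threshold(self):
        cls, sims, ids = _separable_toy()
        tuned = optimize_threshold(cls, sims, ids, folds=3, random_state=0)
        assert tuned.threshold == pytest.approx(1.0)
        assert tuned.cv_fscore == pytest.approx(1.0)
        assert tuned.cv_precision == pytest.approx(1.0)
        assert tuned.cv_auc == pytest.approx(1.0)

    def test_threshold_lies_on_grid(self):
        cls, sims, ids = _separable_toy()
        tuned = optimize_threshold(cls, sims, ids, folds=3, random_state=0)
        assert any(np.isclose(tuned.threshold, threshold_grid()))

    def test_uninformative_scores_give_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 200
        ids = [f"P{i}" for i in range(n)]
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        sims = pd.DataFrame(m, index=ids, columns=ids)
        members = frozenset(ids[i] for i in rng.choice(n, 50, replace=False))
        tuned = optimize_threshold(GoClass("t", members), sims, ids,
                                   folds=5, random_state=0)
        assert tuned.cv_auc == pytest.approx(0.5, abs=0.1)

    def test_no_grid_point_beats_selected_threshold(self):
        """Re-scan oracle: pooled F at every grid threshold never strictly
        exceeds the F at the selected threshold."""
        rng = np.random.default_rng(4)
        n = 40
        ids = [f"P{i}" for i in range(n)]
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        # lift within-member similarity so the class is partially learnable
        members = set(ids[:12])
        for i in range(12):
            for j in range(12):
                if i != j:
                    m[i, j] = min(1.0, m[i, j] + 0.4)
        sims = pd.DataFrame(m, index=ids, columns=ids)
        cls = GoClass("t", frozenset(members))
        tuned = optimize_threshold(cls, sims, ids, folds=5, random_state=0)

        labels = np.array([p in members for p in ids])
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        scores, lab = [], []
        arr = sims.to_numpy()
        for tr, te in skf.split(ids, labels):
            midx = tr[labels[tr]]
            scores.extend(arr[np.ix_(te, midx)].mean(axis=1).tolist())
            lab.extend(labels[te].tolist())
        scores, lab = np.array(scores), np.array(lab)

        def pooled_f(t):
            called = scores >= t
            tp = (called & lab).sum()
            fp = (called & ~lab).sum()
            fn = (~called & lab).sum()
            p = tp / (tp + fp) if tp + fp else 0
            r = tp / (tp + fn) if tp + fn else 0
            return 2 * p * r / (p + r) if p + r else 0

        best = max(pooled_f(t) for t in threshold_grid())
        assert tuned.cv_fscore == pytest.approx(best)
        assert pooled_f(tuned.threshold) == pytest.approx(tuned.cv_fscore)

    def test_class_too_small_marked_untrainable(self):
        cls, sims, ids = _separable_toy()
        tiny = GoClass("t", frozenset({"P1"}))
        tuned = optimize_threshold(tiny, sims, ids, folds=3)
        assert not tuned.trainable and tuned.threshold is None


def _toy_training():
    """Four identical [A,B] positives for term t1, four [C]/[D] negatives."""
    X = [da("A", "B", pid=f"M{i}") for i in range(4)]
    X += [da("C", pid="N0"), da("C", pid="N1"), da("D", pid="N2"),
          da("D", pid="N3")]
    y = [["t1"]] * 4 + [[]] * 4
    return X, y


class TestClassifier:
    def test_fit_sets_sklearn_style_attributes(self):
        X, y = _toy_training()
        model = DomainArchitectureGoClassifier(min_members=3, random_state=0).fit(X, y)
        assert model.protein_ids_ == [d.protein_id for d in X]
        assert model.similarity_.shape == (8, 8)
        assert [c.term_id for c in model.classes_] == ["t1"]
        assert model.classes_[0].cv_fscore == pytest.approx(1.0)

    def test_get_set_params_roundtrip(self):
        model = DomainArchitectureGoClassifier(folds=3)
        params = model.get_params()
        assert params["folds"] == 3
        model.set_params(f_min=0.5)
        assert model.f_min == 0.5

    def test_identical_query_predicted_with_full_similarity(self):
        X, y = _toy_training()
        model = DomainArchitectureGoClassifier(min_members=3, random_state=0).fit(X, y)
        preds = model.predict_records([da("A", "B", pid="Q")])
        assert len(preds) == 1
        assert preds[0].term_id == "t1"
        assert preds[0].mean_similarity == pytest.approx(1.0)

    def test_nine_domain_query_excluded(self):
        X, y = _toy_training()
        model = DomainArchitectureGoClassifier(min_members=3, random_state=0).fit(X, y)
        big = da(*(["A", "B"] * 4 + ["C"]), pid="Q9")  # 9 real domains
        assert model.predict_records([big]) == []

    def test_low_fscore_class_never_emitted(self):
        X, y = _toy_training()
        model = DomainArchitectureGoClassifier(min_members=3, random_state=0).fit(X, y)
        weak = GoClass("t2", frozenset(f"M{i}" for i in range(4)),
                       threshold=0.0, cv_fscore=0.65)
        model.classes_ = list(model.classes_) + [weak]
        preds = model.predict_records([da("A", "B", pid="Q")], f_min=0.7)
        assert {p.term_id for p in preds} == {"t1"}

    def test_no_duplicate_terms_per_protein(self):
        X, y = _toy_training()
        model = DomainArchitectureGoClassifier(min_members=3, random_state=0).fit(X, y)
        preds = model.predict_records([da("A", "B", pid="Q"),
                                       da("A", pid="R")])
        seen = {(p.protein_id, p.term_id) for p in preds}
        assert len(seen) == len(preds)

    def test_novel_query_domains_do_not_crash(self):
        X, y = _toy_training()
        model = DomainArchitectureGoClassifier(min_members=3, random_state=0).fit(X, y)
        preds = model.predict_records([da("A", "B", "ZZZ", pid="Q")])
        assert isinstance(preds, list)  # lenient weighting path

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            DomainArchitectureGoClassifier().predict([da("A")])


class TestTrainWrapper:
    def test_empty_annotations_give_zero_classes(self):
        das = {"P1": da("A", pid="P1"), "P2": da("B", pid="P2")}
        model = train(das, _annset([]))
        assert model.classes_ == []

    def test_single_class_matches_direct_optimization(self):
        X, y = _toy_training()
        das = {d.protein_id: d for d in X}
        pairs = [(d.protein_id, t) for d, terms in zip(X, y) for t in terms]
        model = train(das, _annset(pairs), min_members=3, random_state=0)
        direct = optimize_threshold(
            GoClass("t1", frozenset(d.protein_id for d in X[:4])),
            model.similarity_, model.protein_ids_, folds=5, random_state=0)
        cls = model.classes_[0]
        assert cls.threshold == direct.threshold
        assert cls.cv_fscore == direct.cv_fscore
        assert cls.cv_auc == direct.cv_auc

    def test_predict_wrapper_applies_filters(self):
        X, y = _toy_training()
        das = {d.protein_id: d for d in X}
        pairs = [(d.protein_id, t) for d, terms in zip(X, y) for t in terms]
        model = train(das, _annset(pairs), min_members=3, random_state=0)
        preds = predict(model, [da("A", "B", pid="Q")], f_min=0.7)
        assert preds and preds[0].threshold <= preds[0].mean_similarity


class TestPersistence:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        X, y = _toy_training()
        model = DomainArchitectureGoClassifier(min_members=3, random_state=0).fit(X, y)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        q = [da("A", "B", pid="Q"), da("C", pid="R")]
        assert back.predict_records(q) == model.predict_records(q)
        a, b = back.get_params(), model.get_params()
        # a default (None) scoring reloads as the explicit default params
        assert a.pop("scoring") == (b.pop("scoring") or ScoringParams())
        assert a == b
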