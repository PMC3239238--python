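import numpy as np
import pandas as pd
import pytest

import wagep
from wagep import synthetic as syn
from wagep.errors import ConfigError, EmptySelectionError
from wagep.validation import (
    CohortResult,
    accuracy_curve,
    classify_cohort,
    gene_retention,
    loocv,
    per_class_metrics,
    threshold_accuracy,
)


def _cohort_result(pairs, accept=("exact", "similar")):
    """CohortResult from (best_score, correct) pairs — enough for the
    curve/threshold operations."""
    rows = []
    for i, (score, correct) in enumerate(pairs):
        rows.append(
            {
                "truth": "t",
                "best": "t" if correct else "x",
                "best_score": score,
                "second": None,
                "second_score": np.nan,
                "category": "exact" if correct else "incorrect",
                "tier": "low",
                "correct": bool(correct),
            }
        )
    return CohortResult(pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))]), accept)


class TestLoocv:
    def test_separable_classes_fully_recovered(self, separable_cohort):
        em, annot = separable_cohort
        res = loocv(em, annot, method="wagep")
        assert res.exact_accuracy() == 1.0
        assert (res.table["category"] == "exact").all()
        assert len(res.table) == len(em.sample_ids)

    def test_holdout_class_size_bookkeeping(self, separable_cohort):
        em, annot = separable_cohort
        res = loocv(em, annot, method="wagep")
        assert (res.table["n_class_holdout"] == 9).all()

    def test_small_class_skipped_with_reason(self, separable_cohort):
        em, annot = separable_cohort
        res = loocv(em, annot, min_class_n=10, method="wagep")
        assert len(res.table) == 0 or len(res.skipped) > 0
        assert len(res.skipped) == len(em.sample_ids)  # every class has exactly 10

    def test_deterministic(self, separable_cohort):
        em, annot = separable_cohort
        a = loocv(em, annot, method="wagep").table
        b = loocv(em, annot, method="wagep").table
        pd.testing.assert_frame_equal(a, b)

    def test_both_methods_share_folds(self, separable_cohort):
        em, annot = separable_cohort
        res = loocv(em, annot, method="both")
        assert set(res) == {"wagep", "agep"}
        assert list(res["wagep"].table.index) == list(res["agep"].table.index)

    def test_agrees_with_from_scratch_fold_rebuild(self):
        """Independent brute-force check: every fold rebuilt through the
        public API (build_reference + weight_matrix + scoring) must
        reproduce the harness's per-sample prediction exactly."""
        sc = syn.scenario(
            "easy", seed=29, n_classes=3, n_genes=40, markers_per_class=5, samples_per_class=8
        )
        em, annot, _ = syn.simulate_reference(sc)
        res = loocv(em, annot, method="wagep")
        model = wagep.build_reference(em, annot)
        for sid in em.sample_ids:
            reduced_annot = wagep.SampleAnnotation(
                classes={s: c for s, c in annot.classes.items() if s != sid}
            )
            fold = wagep.build_reference(em.drop_sample(sid), reduced_annot, grid_from=model)
            W = wagep.weight_matrix(fold)
            ts = wagep.ts_score(wagep.tm_score(fold, em.sample_values(sid)))
            brute = wagep.classify(wagep.similarity(ts, W), annot.class_of(sid))
            row = res.table.loc[sid]
            assert brute.best == row["best"]
            assert brute.best_score == row["best_score"]  # bit-identical path
            assert brute.category == row["category"]


class TestPerClassMetrics:
    def test_all_correct(self, separable_cohort):
        em, annot = separable_cohort
        res = loocv(em, annot, method="wagep")
        m = per_class_metrics(res)
        body = m.drop(index="Total/average")
        assert (body["sensitivity"] == 1.0).all()
        assert (body["specificity"] == 1.0).all()
        assert m.loc["Total/average", "percent_correct"] == 100.0

    def test_never_predicted_class(self):
        pairs = [(0.2, True)] * 3
        res = _cohort_result(pairs)
        # add a class never predicted: truth 'u', predicted 't'
        extra = res.table.iloc[[0]].copy()
        extra.index = ["u0"]
        extra["truth"] = "u"
        extra["category"] = "incorrect"
        extra["correct"] = False
        res = CohortResult(pd.concat([res.table, extra]), res.accept)
        m = per_class_metrics(res)
        assert m.loc["u", "sensitivity"] == 0.0
        assert m.loc["u", "specificity"] == 1.0

    def test_matches_hand_computed_confusion(self):
        # truth/prediction fixture:  A: 2/3 correct; B: 1/2; C: 0/1
        rows = [
            ("A", "A", True), ("A", "A", True), ("A", "B", False),
            ("B", "B", True), ("B", "C", False),
            ("C", "A", False),
        ]
        table = pd.DataFrame(
            [
                {
                    "truth": t, "best": p, "best_score": 0.1, "second": None,
                    "second_score": np.nan, "category": "exact" if ok else "incorrect",
                    "tier": "low", "correct": ok,
                }
                for t, p, ok in rows
            ],
            index=[f"s{i}" for i in range(len(rows))],
        )
        m = per_class_metrics(CohortResult(table, ("exact",)))
        assert m.loc["A", "sensitivity"] == pytest.approx(2 / 3)
        assert m.loc["B", "sensitivity"] == pytest.approx(1 / 2)
        assert m.loc["C", "sensitivity"] == 0.0
        # specificity: A predicted for 1 of 3 non-A; B for 1 of 4 non-B; C for 1 of 5 non-C
        assert m.loc["A", "specificity"] == pytest.approx(1 - 1 / 3)
        assert m.loc["B", "specificity"] == pytest.approx(1 - 1 / 4)
        assert m.loc["C", "specificity"] == pytest.approx(1 - 1 / 5)
        assert m.loc["Total/average", "percent_correct"] == pytest.approx(100 * 3 / 6)


class TestAccuracyCurve:
    def test_all_correct_every_window_one(self):
        res = _cohort_result([(0.01 * i, True) for i in range(20)])
        curve = accuracy_curve(res)
        assert np.all(curve.accuracy[curve.counts > 0] == 1.0)

    def test_all_incorrect_every_window_zero(self):
        res = _cohort_result([(0.01 * i, False) for i in range(20)])
        curve = accuracy_curve(res)
        assert np.all(curve.accuracy[curve.counts > 0] == 0.0)

    def test_matches_brute_force_window_oracle(self):
        rng = np.random.default_rng(47)
        pairs = [(float(rng.uniform(-0.05, 0.5)), bool(rng.random() < 0.7)) for _ in range(20)]
        res = _cohort_result(pairs)
        curve = accuracy_curve(res, width=0.1, step=0.005)
        scores = np.array([p[0] for p in pairs])
        correct = np.array([p[1] for p in pairs])
        for edge, acc, cnt in zip(curve.left_edges, curve.accuracy, curve.counts):
            inside = (scores >= edge) & (scores < edge + 0.1)
            assert cnt == inside.sum()
            if cnt:
                assert acc == pytest.approx(correct[inside].mean())
            else:
                assert np.isnan(acc)

    def test_single_full_range_window_equals_overall_accuracy(self):
        pairs = [(0.02 * i, i % 3 != 0) for i in range(15)]
        res = _cohort_result(pairs)
        curve = accuracy_curve(res, width=10.0, step=100.0)
        assert curve.accuracy[0] == pytest.approx(res.accuracy)

    def test_invalid_window_config(self):
        res = _cohort_result([(0.1, True)])
        with pytest.raises(ConfigError):
            accuracy_curve(res, width=0.0)
        with pytest.raises(ConfigError):
            accuracy_curve(res, step=-1.0)


class TestThresholdAccuracy:
    def test_below_minimum_gives_overall(self):
        pairs = [(0.1, True), (0.2, True), (0.3, False)]
        res = _cohort_result(pairs)
        frac, acc = threshold_accuracy(res, -1.0)
        assert frac == 1.0 and acc == pytest.approx(2 / 3)

    def test_above_maximum_undefined(self):
        res = _cohort_result([(0.1, True)])
        frac, acc = threshold_accuracy(res, 0.5)
        assert frac == 0.0 and np.isnan(acc)

    def test_matches_hand_count(self):
        pairs = [
            (0.01, False), (0.03, True), (0.06, False), (0.07, True), (0.09, True),
            (0.11, True), (0.12, True), (0.15, False), (0.2, True), (0.3, True),
        ]
        res = _cohort_result(pairs)
        frac, acc = threshold_accuracy(res, 0.1)
        assert frac == pytest.approx(5 / 10)
        assert acc == pytest.approx(4 / 5)


@pytest.fixture(scope="module")
def setup():
    sc = syn.scenario(
        "easy", seed=53, n_classes=3, n_genes=60, markers_per_class=10, samples_per_class=15
    )
    em, annot, markers = syn.simulate_reference(sc)
    model = wagep.build_reference(em, annot)
    W = wagep.weight_matrix(model)
    return sc, model, W, markers


class TestGeneRetention:
    def test_typical_member_scores_high(self, setup):
        sc, model, W, markers = setup
        cls = sc.class_labels[0]
        queries, _ = syn.simulate_metastasis(sc, cls, n_queries=3, drift=0.0)
        table, sims = gene_retention(model, W, queries, cls)
        assert (table.mean(axis=0) > 0.0).all()  # every query leans positive
        assert table.mean().mean() > 0.2
        assert (sims > 0).all()

    def test_drifted_markers_scored_below_retained(self, setup):
        """Reverting half the markers to background drops their ts-scores
        below the retained markers' (seeded drift simulation oracle)."""
        sc, model, W, markers = setup
        cls = sc.class_labels[0]
        diffs = []
        for stream in range(2, 7):
            queries, drifted = syn.simulate_metastasis(
                sc, cls, n_queries=4, drift=0.5, stream=stream
            )
            table, _ = gene_retention(model, W, queries, cls)
            for sid in queries.sample_ids:
                dr = [g for g in drifted[sid] if g in table.index]
                kept = [g for g in table.index if g not in drifted[sid]]
                diffs.append(table.loc[kept, sid].mean() - table.loc[dr, sid].mean())
        assert np.mean(diffs) > 0

    def test_queries_ordered_by_similarity(self, setup):
        sc, model, W, _ = setup
        cls = sc.class_labels[1]
        queries, _ = syn.simulate_metastasis(sc, cls, n_queries=5, drift=0.3)
        _, sims = gene_retention(model, W, queries, cls)
        assert list(sims) == sorted(sims, reverse=True)

    def test_gene_missing_in_one_query_excluded_for_all(self, setup):
        sc, model, W, markers = setup
        cls = sc.class_labels[0]
        queries, _ = syn.simulate_metastasis(sc, cls, n_queries=3, drift=0.0)
        victim = wagep.specific_genes(W, cls)[0]
        vals = queries.values.copy()
        vals[list(queries.gene_ids).index(victim), 1] = np.nan
        holey = wagep.ExpressionMatrix(vals, queries.gene_ids, queries.sample_ids)
        table, _ = gene_retention(model, W, holey, cls)
        assert victim not in table.index

    def test_no_gene_above_threshold_raises(self, setup):
        _, model, W, _ = setup
        with pytest.raises(EmptySelectionError):
            gene_retention(model, W.clip(upper=0.1), None, model.class_labels[0])


def test_classify_cohort_against_fixed_model(small_model, small_weights, small_scenario):
    qem, truth, _ = syn.simulate_query_cohort(small_scenario, n_per_class=2, drift=0.0)
    res = classify_cohort(small_model, small_weights, qem, truth)
    assert len(res.table) == len(qem.sample_ids)
    assert res.accuracy > 0.9
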