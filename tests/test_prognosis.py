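import math

import numpy as np
import pandas as pd
import pytest

from tregsig import (
    SignatureModel,
    SplitSpec,
    SurvSimConfig,
    evaluate_groups,
    grade_stratified_evaluation,
    pan_cohort_evaluation,
    predict_outcome_groups,
    simulate_survival_cohort,
    split_cohort,
    train_survival_classifier,
)

from conftest import make_survival

LN2 = math.log(2)


class TestSplit:
    def test_printed_split_arithmetic(self):
        co = simulate_survival_cohort(SurvSimConfig(n_samples=533, n_genes=5, seed=0))
        train, test = split_cohort(co, SplitSpec(train_fraction=0.10, seed=1))
        assert (train.n_samples, test.n_samples) == (53, 480)

    def test_floor_rule_small_n(self):
        co = simulate_survival_cohort(SurvSimConfig(n_samples=10, n_genes=5, seed=0))
        train, test = split_cohort(co, SplitSpec(train_fraction=0.10, seed=1))
        assert (train.n_samples, test.n_samples) == (1, 9)

    def test_deterministic_and_exhaustive(self):
        co = simulate_survival_cohort(SurvSimConfig(n_samples=60, n_genes=5, seed=0))
        a1, b1 = split_cohort(co, SplitSpec(seed=5))
        a2, b2 = split_cohort(co, SplitSpec(seed=5))
        assert list(a1.samples) == list(a2.samples)
        assert set(a1.samples) | set(b1.samples) == set(co.samples)
        assert not set(a1.samples) & set(b1.samples)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError, match="train_fraction"):
            SplitSpec(train_fraction=1.0)
        co = simulate_survival_cohort(SurvSimConfig(n_samples=5, n_genes=5, seed=0))
        with pytest.raises(ValueError, match="degenerate"):
            split_cohort(co, SplitSpec(train_fraction=0.05))


def _separable_cohort(n=20, seed=0):
    rng = np.random.default_rng(seed)
    event = np.array([0, 1] * (n // 2))
    expr = rng.normal(size=(6, n)) * 0.1 + event * 3.0
    return make_survival(time=rng.exponential(2, n) + 0.1, event=event, expr=expr)


class TestClassifier:
    def test_separable_training_accuracy(self):
        co = _separable_cohort()
        model = train_survival_classifier(co, list(co.genes))
        d = model.decision_values(co)
        pred = (d > 0).astype(int)
        assert (pred == co.event.to_numpy()).all()
        assert model.cost in (0.01, 0.1, 1.0, 10.0, 100.0)

    def test_single_class_rejected(self):
        co = make_survival([1, 2, 3], [1, 1, 1], expr=np.random.default_rng(0).normal(size=(2, 3)))
        with pytest.raises(ValueError, match="single class"):
            train_survival_classifier(co, list(co.genes))

    def test_null_features_cv_accuracy_near_majority(self):
        rng = np.random.default_rng(11)
        n = 200
        event = (rng.random(n) < 0.65).astype(int)
        co = make_survival(rng.exponential(2, n), event, expr=rng.normal(size=(6, n)))
        from sklearn.model_selection import cross_val_score
        from sklearn.svm import SVC

        model = train_survival_classifier(co, list(co.genes))
        z = (co.expr.to_numpy() - model.means[:, None]) / model.sds[:, None]
        acc = cross_val_score(SVC(kernel="linear", C=model.cost), z.T, event, cv=5).mean()
        assert abs(acc - max(event.mean(), 1 - event.mean())) < 0.1

    def test_duplicated_training_set_same_weights(self):
        co = _separable_cohort(seed=3)
        doubled = make_survival(
            np.concatenate([co.time, co.time]),
            np.concatenate([co.event, co.event]),
            expr=np.concatenate([co.expr.to_numpy(), co.expr.to_numpy()], axis=1),
        )
        # at a fixed large cost the separable fit has zero slack, so the
        # max-margin solution is unchanged by duplication
        m1 = train_survival_classifier(co, list(co.genes), cost_grid=(100.0,))
        m2 = train_survival_classifier(doubled, list(doubled.genes), cost_grid=(100.0,))
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-4)

    def test_json_round_trip(self, tmp_path):
        co = _separable_cohort(seed=4)
        model = train_survival_classifier(co, list(co.genes))
        model.to_json(tmp_path / "m.json")
        back = SignatureModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.weights, model.weights)
        np.testing.assert_allclose(back.decision_values(co), model.decision_values(co))


class TestPredict:
    def _toy_model(self):
        return SignatureModel(
            genes=["gA", "gB"],
            means=np.array([0.0, 0.0]),
            sds=np.array([1.0, 1.0]),
            weights=np.array([1.0, 0.0]),
            intercept=0.0,
            cost=1.0,
        )

    def test_zero_decision_is_good(self):
        co = make_survival([1, 2], [1, 0], expr=np.array([[0.0, 2.0], [5.0, -5.0]]), genes=["gA", "gB"])
        groups = predict_outcome_groups(self._toy_model(), co)
        assert groups.tolist() == ["good", "poor"]

    def test_missing_gene_named(self):
        co = make_survival([1, 2], [1, 0], expr=np.zeros((1, 2)), genes=["gA"])
        with pytest.raises(ValueError, match="gB"):
            predict_outcome_groups(self._toy_model(), co)

    def test_held_out_poor_group_has_more_events(self):
        cfg = SurvSimConfig(
            n_samples=600, n_genes=10, planted_prognostic=[(i, LN2) for i in range(6)],
            baseline_hazard=0.1, censoring_hazard=0.05, seed=8,
        )
        co = simulate_survival_cohort(cfg)
        train, test = split_cohort(co, SplitSpec(train_fraction=0.3, seed=0))
        model = train_survival_classifier(train, list(co.genes[:6]))
        groups = predict_outcome_groups(model, test)
        poor = groups == "poor"
        assert poor.any() and (~poor).any()
        import scipy.stats

        tab = [
            [int(test.event[poor].sum()), int((1 - test.event[poor]).sum())],
            [int(test.event[~poor].sum()), int((1 - test.event[~poor]).sum())],
        ]
        assert scipy.stats.fisher_exact(tab, alternative="greater").pvalue < 0.01


def _two_group_cohort(n=500, hr=2.0, seed=0, censor=0.3):
    rng = np.random.default_rng(seed)
    poor = rng.random(n) < 0.5
    h = 0.1 * np.where(poor, hr, 1.0)
    t_event = rng.exponential(1 / h)
    t_cens = rng.exponential(1 / 0.03, n) if censor else np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    co = make_survival(time, event, expr=np.zeros((1, n)))
    groups = pd.Series(np.where(poor, "poor", "good"), index=co.samples)
    return co, groups


class TestEvaluate:
    def test_km_starts_at_one_and_monotone(self):
        co, groups = _two_group_cohort(n=120, seed=1)
        ev = evaluate_groups(co, groups)
        for label, km in ev.km.items():
            vals = km.iloc[:, 0].to_numpy()
            assert km.iloc[0, 0] == 1.0
            assert np.all(np.diff(vals) <= 1e-12)

    def test_large_n_log_hr_near_truth(self):
        co, groups = _two_group_cohort(n=5000, hr=2.0, seed=2)
        ev = evaluate_groups(co, groups)
        assert math.log(ev.hr) == pytest.approx(LN2, abs=0.1)
        assert ev.ci95[0] < ev.hr < ev.ci95[1]
        assert ev.logrank_p < 1e-10

    def test_label_swap_inverts_hr(self):
        co, groups = _two_group_cohort(n=300, seed=3)
        swapped = groups.map({"poor": "good", "good": "poor"})
        ev1 = evaluate_groups(co, groups)
        ev2 = evaluate_groups(co, swapped)
        assert ev1.hr == pytest.approx(1 / ev2.hr, rel=1e-6)
        assert ev1.logrank_p == pytest.approx(ev2.logrank_p, rel=1e-9)

    def test_null_groups_usually_not_significant(self):
        hits = 0
        for seed in range(30):
            co, groups = _two_group_cohort(n=200, hr=1.0, seed=seed)
            hits += evaluate_groups(co, groups).logrank_p < 0.05
        assert hits <= 4  # ~alpha of 30 null replicates

    def test_errors(self):
        co, groups = _two_group_cohort(n=50, seed=4)
        with pytest.raises(ValueError, match="nonempty"):
            evaluate_groups(co, pd.Series("poor", index=co.samples))
        no_events = make_survival([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            evaluate_groups(no_events, pd.Series(["good", "poor"], index=no_events.samples))


class TestPanCohort:
    def test_single_cohort_matches_evaluate_groups(self):
        cfg = SurvSimConfig(
            n_samples=600, n_genes=10, planted_prognostic=[(i, LN2) for i in range(6)],
            baseline_hazard=0.1, censoring_hazard=0.05, seed=8,
        )
        co = simulate_survival_cohort(cfg)
        train, test = split_cohort(co, SplitSpec(train_fraction=0.3, seed=0))
        model = train_survival_classifier(train, list(co.genes[:6]))
        evals, table = pan_cohort_evaluation([test], model)
        direct = evaluate_groups(test, predict_outcome_groups(model, test))
        assert table.loc[test.cohort, "hr"] == pytest.approx(direct.hr)
        assert table.loc[test.cohort, "logrank_p"] == pytest.approx(direct.logrank_p)

    def test_missing_genes_flagged_not_dropped(self):
        cfg = SurvSimConfig(
            n_samples=600, n_genes=10, planted_prognostic=[(i, LN2) for i in range(6)],
            baseline_hazard=0.1, censoring_hazard=0.05, seed=8,
        )
        co = simulate_survival_cohort(cfg)
        train, test = split_cohort(co, SplitSpec(train_fraction=0.3, seed=0))
        model = train_survival_classifier(train, list(co.genes[:6]))
        alien = make_survival([1, 2, 3], [1, 0, 1], expr=np.zeros((1, 3)), genes=["ZZZ"], cohort="alien")
        _, table = pan_cohort_evaluation([test, alien], model)
        assert len(table) == 2
        assert not table.loc["alien", "evaluable"]
        assert "missing" in table.loc["alien", "note"]

    def test_signal_detected_only_where_planted(self):
        model_cfg = SurvSimConfig(
            n_samples=400, n_genes=8, planted_prognostic=[(i, LN2) for i in range(4)], seed=6
        )
        master = simulate_survival_cohort(model_cfg)
        train, _ = split_cohort(master, SplitSpec(train_fraction=0.5, seed=0))
        model = train_survival_classifier(train, list(master.genes[:4]))
        cohorts = []
        for i, planted in enumerate([True, False, True, False, False]):
            cfg = SurvSimConfig(
                n_samples=300,
                n_genes=8,
                planted_prognostic=[(j, LN2) for j in range(4)] if planted else [],
                seed=20 + i,
                cohort=f"c{i}",
            )
            cohorts.append(simulate_survival_cohort(cfg))
        _, table = pan_cohort_evaluation(cohorts, model)
        sig = table[(table["hr"] > 1) & (table["logrank_p"] < 0.05)]
        assert set(sig.index) == {"c0", "c2"}

    def test_empty_cohort_list_rejected(self):
        with pytest.raises(ValueError, match="no cohorts"):
            pan_cohort_evaluation([], None)


class TestGradeStratified:
    def test_uniform_grade_equals_unstratified(self):
        co, groups = _two_group_cohort(n=200, seed=7)
        co.grade = pd.Series(3, index=co.samples)
        ev = grade_stratified_evaluation(co, groups, 3)
        full = evaluate_groups(co, groups)
        assert ev.hr == pytest.approx(full.hr)

    def test_signal_only_in_grade3_stratum(self):
        co3, g3 = _two_group_cohort(n=400, hr=3.0, seed=8)
        co1, g1 = _two_group_cohort(n=400, hr=1.0, seed=9)
        co = make_survival(
            np.concatenate([co3.time, co1.time]),
            np.concatenate([co3.event, co1.event]),
            expr=np.zeros((1, 800)),
            grade=[3] * 400 + [1] * 400,
        )
        groups = pd.Series(
            np.concatenate([g3.to_numpy(), g1.to_numpy()]), index=co.samples
        )
        ev3 = grade_stratified_evaluation(co, groups, 3)
        ev1 = grade_stratified_evaluation(co, groups, 1)
        assert ev3.logrank_p < 0.05 < ev1.logrank_p
        assert ev3.hr > 1.5

    def test_missing_grade_errors(self):
        co, groups = _two_group_cohort(n=50, seed=10)
        with pytest.raises(ValueError, match="no grade"):
            grade_stratified_evaluation(co, groups, 3)
        co.grade = pd.Series(2, index=co.samples)
        with pytest.raises(ValueError, match="grade 5"):
            grade_stratified_evaluation(co, groups, 5)
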