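"""ROC/AUC machinery and the LOOCV association protocol."""

import numpy as np
import pandas as pd
import pytest

from lncsurv import (
    AssociationDataset,
    EvaluationError,
    MlrLDAcp,
    loocv_association,
    roc_auc,
    survival_roc,
)


def mann_whitney_auc(scores, labels):
    """Independent oracle: explicit concordant-pair counting, ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([3, 2, 1], [1, 1, 0], 1.0),
            ([1, 1, 1, 1], [1, 0, 1, 0], 0.5),
            ([0.9, 0.8, 0.3], [1, 0, 1], 0.5),  # one concordant, one discordant pair
        ],
    )
    def test_small_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(10):
            scores = rng.normal(size=40)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max():
                continue
            curve = roc_auc(scores, labels)
            assert abs(curve.auc - mann_whitney_auc(scores, labels)) < 1e-12

    def test_tied_scores_match_mann_whitney(self, rng):
        scores = rng.integers(0, 4, size=60).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=60)
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_curve_monotone(self, rng):
        curve = roc_auc(rng.normal(size=50), rng.integers(0, 2, size=50))
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()
        assert 0.0 <= curve.auc <= 1.0

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([1.0, 2.0], [1, 1])


@pytest.fixture(scope="module")
def fitted(strong_cohort):
    model = MlrLDAcp.from_cohort(strong_cohort.normal, strong_cohort.tumor,
                                 strong_cohort.clinical)
    return model, model.fit()


class TestSurvivalRoc:
    def test_strong_model_separates_five_year_survival(self, strong_cohort, fitted):
        model, res = fitted
        curve = survival_roc(res, model.exog, strong_cohort.clinical, horizon=1825)
        assert curve.auc > 0.95

    def test_horizon_must_be_positive(self, strong_cohort, fitted):
        model, res = fitted
        with pytest.raises(EvaluationError):
            survival_roc(res, model.exog, strong_cohort.clinical, horizon=0)

    def test_indeterminate_censored_patients_are_excluded(self, strong_cohort, fitted):
        model, res = fitted
        clin = strong_cohort.clinical.copy()
        # an alive patient with short follow-up carries no 5-year label
        clin.loc[clin.index[0], ["vital_status", "days_to_death", "days_to_last_follow_up"]] = (
            "alive", np.nan, 100.0,
        )
        n_before = len(survival_roc(res, model.exog, strong_cohort.clinical).tpr)
        curve = survival_roc(res, model.exog, clin)
        assert curve.auc > 0.9
        assert len(curve.tpr) <= n_before

    def test_constant_predictor_near_chance(self, rng):
        # an intercept-only score carries no information: AUC ~ 0.5 across seeds
        aucs = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            scores = np.full(80, 5.0) + r.normal(0, 1e-9, 80)  # break exact ties randomly
            labels = r.integers(0, 2, size=80)
            if labels.min() == labels.max():
                continue
            aucs.append(roc_auc(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)


class TestLoocvAssociation:
    @pytest.fixture
    def dataset(self):
        lncs = tuple(f"L{i}" for i in range(12))
        pairs = tuple((f"L{i}", "prostate") for i in range(4))
        return AssociationDataset(pairs=pairs, universe=lncs, diseases=("prostate",))

    def test_oracle_scorer_gives_perfect_auc(self, dataset):
        known = set(dataset.pairs)

        def scorer(train):
            return {p: (1.0 if p in known else 0.0) for p in dataset.all_pairs()}

        assert loocv_association(dataset, scorer).auc == 1.0

    def test_scorer_invoked_once_per_known_pair(self, dataset):
        calls = []

        def scorer(train):
            calls.append(tuple(train))
            return {p: 0.5 + 0.001 * hash(p) % 7 for p in dataset.all_pairs()}

        loocv_association(dataset, scorer)
        assert len(calls) == len(dataset.pairs)
        for train in calls:
            assert len(train) == len(dataset.pairs) - 1

    def test_random_scorer_near_chance(self):
        lncs = tuple(f"L{i}" for i in range(50))
        pairs = tuple((f"L{i}", "d") for i in range(20))
        dataset = AssociationDataset(pairs=pairs, universe=lncs, diseases=("d",))
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)

            def scorer(train, r=r):
                return {p: r.uniform() for p in dataset.all_pairs()}

            aucs.append(loocv_association(dataset, scorer).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_scorer_failure_names_the_fold(self, dataset):
        def scorer(train):
            raise RuntimeError("boom")

        with pytest.raises(EvaluationError, match="fold 0"):
            loocv_association(dataset, scorer)

    def test_model_scorer_ranks_planted_associations(self, strong_cohort):
        """End-to-end: standardized |theta| from refits ranks planted causal
        transcripts above non-causal candidates."""
        c = strong_cohort
        model = MlrLDAcp.from_cohort(c.normal, c.tumor, c.clinical)
        res = model.fit()
        scores = res.association_scores()
        causal = c.truth["causal_transcripts"]
        pairs = tuple((t, "prostate") for t in causal)
        dataset = AssociationDataset(pairs=pairs, universe=tuple(scores.index),
                                     diseases=("prostate",))

        def scorer(train):
            return {(t, "prostate"): float(scores[t]) for t in scores.index}

        assert loocv_association(dataset, scorer).auc > 0.9

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(EvaluationError):
            AssociationDataset(pairs=(("L1", "d"), ("L1", "d")),
                               universe=("L1",), diseases=("d",))
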