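"""Threshold classifiers, evaluation metrics and centroid subtype calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netstrat.classify import (
    GREATER,
    INDETERMINATE,
    call_subtype,
    classification_metrics,
    fit_threshold_classifier,
    rescue_indeterminate,
)
from netstrat.containers import CentroidModel, DataError

from oracles import confusion_metrics_brute


def _series(values, prefix="s"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestFitThresholdClassifier:
    def test_separable_cohort_reaches_perfect_training_accuracy(self):
        scores = _series([1, 2, 3, 4, 5, 10, 11, 12, 13, 14, 15, 16, 17], prefix="p")
        labels = _series([False] * 5 + [True] * 8, prefix="p")
        clf = fit_threshold_classifier(scores, labels, seed=0)
        assert not clf.degenerate
        assert 5 < clf.cutoff < 10
        assert clf.direction == GREATER
        pred = clf.predict(scores)
        assert (pred == labels).all()

    def test_cutoff_is_midpoint_between_observed_values(self):
        scores = _series([0, 1, 2, 3, 10, 11, 12, 13])
        labels = _series([False] * 4 + [True] * 4)
        clf = fit_threshold_classifier(scores, labels, min_leaf=3, seed=0)
        assert clf.cutoff == pytest.approx(6.5)  # midpoint of 3 and 10

    def test_null_labels_usually_give_no_split(self):
        rng = np.random.default_rng(5)
        n_split = 0
        n_sim = 120
        for i in range(n_sim):
            scores = _series(rng.normal(size=13))
            labels = _series(rng.permutation([True] * 8 + [False] * 5))
            clf = fit_threshold_classifier(scores, labels, n_perm=400, seed=i)
            n_split += not clf.degenerate
        # type-I control at alpha = 0.05 within 3 binomial standard errors
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert n_split / n_sim <= 0.05 + 3 * se

    def test_degenerate_model_predicts_majority(self):
        rng = np.random.default_rng(0)
        scores = _series(rng.normal(size=12))
        labels = _series([True] * 8 + [False] * 4)
        clf = fit_threshold_classifier(scores, _series(rng.permutation(labels)), seed=1)
        if clf.degenerate:
            assert clf.predict(scores).all()  # majority class is responder

    def test_tie_at_cutoff_goes_low_side(self):
        scores = _series([0.0, 1, 2, 3, 10, 11, 12, 13])
        labels = _series([False] * 4 + [True] * 4)
        clf = fit_threshold_classifier(scores, labels, min_leaf=3, seed=0)
        at_cut = pd.Series([clf.cutoff], index=["x"])
        assert not clf.predict(at_cut).iloc[0]  # <= cutoff -> non-responder side

    def test_one_class_labels_rejected(self):
        scores = _series(np.arange(8.0))
        with pytest.raises(DataError):
            fit_threshold_classifier(scores, _series([True] * 8), seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataError):
            fit_threshold_classifier(
                _series([1.0, 2, 3, 4, 5]), _series([True, False, True, False, True]),
                min_leaf=3, seed=0,
            )

    def test_planted_threshold_recovered_in_straddling_gap(self):
        rng = np.random.default_rng(42)
        hits = 0
        for i in range(30):
            resp = np.zeros(13, dtype=bool)
            resp[:8] = True
            resp = rng.permutation(resp)
            offs = 2.0 * rng.uniform(0.1, 1.0, 13)
            scores = np.where(resp, offs, -offs)  # threshold at 0
            s = _series(scores)
            clf = fit_threshold_classifier(s, _series(resp), n_perm=2000, seed=i)
            lo = scores[~resp].max()
            hi = scores[resp].min()
            if not clf.degenerate and lo < clf.cutoff < hi:
                hits += 1
        assert hits >= 28


class TestMetrics:
    def test_perfect_prediction(self):
        pred = _series([True] * 8 + [False] * 5)
        m = classification_metrics(pred, pred)
        assert m == {"accuracy": 1.0, "mcc": 1.0, "f1": 1.0}

    def test_single_class_predictor_reports_na(self):
        # majority-class predictor on a 8/5 cohort: accuracy 61.5%, MCC/F1 N/A
        truth = _series([True] * 8 + [False] * 5)
        pred = _series([True] * 13)
        m = classification_metrics(pred, truth)
        assert m["accuracy"] == pytest.approx(8 / 13)
        assert m["mcc"] is None
        assert m["f1"] == pytest.approx(2 * (8 / 13) / (1 + 8 / 13))
        # all-negative predictor: no positives anywhere -> F1 undefined too
        m2 = classification_metrics(~pred.astype(bool), truth)
        assert m2["mcc"] is None and m2["f1"] is None

    def test_matches_enumeration_of_all_small_confusion_tables(self):
        for n in range(1, 7):
            for pred_bits in itertools.product([False, True], repeat=n):
                for true_bits in itertools.product([False, True], repeat=n):
                    pred = _series(list(pred_bits))
                    truth = _series(list(true_bits))
                    m = classification_metrics(pred, truth)
                    tp = sum(p and t for p, t in zip(pred_bits, true_bits))
                    tn = sum(not p and not t for p, t in zip(pred_bits, true_bits))
                    fp = sum(p and not t for p, t in zip(pred_bits, true_bits))
                    fn = sum(not p and t for p, t in zip(pred_bits, true_bits))
                    acc, mcc, f1 = confusion_metrics_brute(tp, tn, fp, fn)
                    assert m["accuracy"] == pytest.approx(acc)
                    if mcc is None:
                        assert m["mcc"] is None
                    else:
                        assert m["mcc"] == pytest.approx(mcc)
                    if f1 is None:
                        assert m["f1"] is None
                    else:
                        assert m["f1"] == pytest.approx(f1)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            classification_metrics(_series([]), _series([]))


@pytest.fixture()
def centroids(rng):
    genes = [f"g{i}" for i in range(77)]
    profiles = pd.DataFrame(
        rng.normal(5, 2, (77, 3)), index=genes, columns=["BLIA", "BLIS", "LAR"]
    )
    return CentroidModel(profiles=profiles)


class TestCallSubtype:
    def test_sample_equal_to_centroid_called(self, centroids):
        sample = centroids.profiles["BLIS"].copy()
        sample.name = "s1"
        call = call_subtype(sample, centroids)
        assert call.call == "BLIS"
        assert call.correlations["BLIS"] == pytest.approx(1.0)

    def test_equidistant_sample_has_zero_margin(self, centroids):
        # build two centroids that are pair-swaps of each other: any sample
        # fixed by the swap is exactly rank-equidistant from both
        a = centroids.profiles["BLIA"].to_numpy().copy()
        swapped = a.copy()
        m = len(a) - (len(a) % 2)  # swap pairs; odd leftover is a fixed point
        swapped[0:m:2], swapped[1:m:2] = a[1:m:2].copy(), a[0:m:2].copy()
        profiles = centroids.profiles.copy()
        profiles["BLIS"] = swapped
        model = CentroidModel(profiles=profiles)
        mid = (profiles["BLIA"] + profiles["BLIS"]) / 2  # invariant under the swap
        mid.name = "mid"
        call = call_subtype(mid, model)
        rho = call.correlations
        assert rho["BLIA"] == pytest.approx(rho["BLIS"], abs=1e-12)
        assert call.call == INDETERMINATE

    def test_margin_rule_boundary(self, centroids, rng):
        # blend towards BLIA until margin crosses the 0.1 rule
        a, b = centroids.profiles["BLIA"], centroids.profiles["BLIS"]
        low = (0.52 * a + 0.48 * b).rename(None)
        low.name = "close"
        high = (0.95 * a + 0.05 * b + rng.normal(0, 0.01, 77)).rename(None)
        high.name = "far"
        c_low = call_subtype(low, centroids)
        c_high = call_subtype(high, centroids)
        assert c_low.margin < 0.1 and c_low.call == INDETERMINATE
        assert c_high.margin > 0.1 and c_high.call == "BLIA"

    def test_monotone_transform_invariance(self, centroids):
        sample = centroids.profiles["LAR"] * 1.0
        sample.name = "s"
        warped = np.exp(sample / 4)
        warped.name = "s"
        assert call_subtype(sample, centroids).call == call_subtype(warped, centroids).call

    def test_constant_sample_indeterminate_with_reason(self, centroids):
        sample = pd.Series(3.0, index=centroids.gene_ids, name="flat")
        call = call_subtype(sample, centroids)
        assert call.call == INDETERMINATE
        assert call.reason == "constant_sample"


class TestRescue:
    def _calls(self, centroids, n_ind, n_det):
        calls = []
        a = centroids.profiles["BLIA"].to_numpy()
        swapped = a.copy()
        m = len(a) - (len(a) % 2)  # swap pairs; odd leftover is a fixed point
        swapped[0:m:2], swapped[1:m:2] = a[1:m:2].copy(), a[0:m:2].copy()
        profiles = centroids.profiles.copy()
        profiles["BLIS"] = swapped
        model = CentroidModel(profiles=profiles)
        for i in range(n_ind):
            s = (profiles["BLIA"] + profiles["BLIS"]) / 2
            s.name = f"ind{i}"
            calls.append(call_subtype(s, model))
        for i in range(n_det):
            s = centroids.profiles["LAR"].copy()
            s.name = f"det{i}"
            calls.append(call_subtype(s, centroids))
        return calls

    def test_all_no_calls_resolved(self, centroids):
        # ~46% indeterminate cohort drops to 0% after rescue
        calls = self._calls(centroids, n_ind=6, n_det=7)
        assert sum(c.call == INDETERMINATE for c in calls) == 6
        pred = pd.Series(
            [i % 2 == 0 for i in range(6)] + [True] * 7,
            index=[c.sample_id for c in calls],
        )
        rescued = rescue_indeterminate(calls, pred)
        assert sum(c.call == INDETERMINATE for c in rescued) == 0
        for c in rescued[:6]:
            assert c.rescue_source == "network_classifier"
            assert c.call in ("BLIA", "BLIS")
        for c in rescued[6:]:
            assert c.rescue_source == "none" and c.call == "LAR"

    def test_identity_when_no_indeterminates(self, centroids):
        calls = self._calls(centroids, n_ind=0, n_det=4)
        rescued = rescue_indeterminate(calls, pd.Series(dtype=bool))
        assert [c.call for c in rescued] == [c.call for c in calls]

    def test_missing_prediction_is_an_error(self, centroids):
        calls = self._calls(centroids, n_ind=1, n_det=0)
        with pytest.raises(DataError):
            rescue_indeterminate(calls, pd.Series(dtype=bool))

    def test_predicted_responders_become_good_prognosis(self, centroids):
        calls = self._calls(centroids, n_ind=3, n_det=0)
        pred = pd.Series(True, index=[c.sample_id for c in calls])
        rescued = rescue_indeterminate(calls, pred)
        assert all(c.call == "BLIA" for c in rescued)
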