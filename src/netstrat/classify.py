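"""Response classification and centroid subtype calling.

The response classifier is a depth-1 conditional-inference threshold
model: a permutation test on the linear statistic sum(score_i *
label_i) gates whether any split is made at all (exact enumeration for
small cohorts, Monte-Carlo otherwise); when the association is
significant the cutoff maximizing the standardized two-sample
statistic over admissible midpoints is chosen, with both leaves
required to hold at least ``min_leaf`` training samples.

Molecular subtypes are called by Spearman correlation against
reference centroid profiles; calls whose top-two correlation margin
falls below 0.1 are INDETERMINATE, and may be rescued by a response
predictor (predicted non-responders to the poor-prognosis subtype,
predicted responders to the good-prognosis one).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import CentroidModel, DataError

__all__ = [
    "ThresholdClassifier",
    "SubtypeCall",
    "fit_threshold_classifier",
    "classification_metrics",
    "call_subtype",
    "rescue_indeterminate",
]

GREATER = "greater_is_responder"
LESSER = "lesser_is_responder"
INDETERMINATE = "INDETERMINATE"


@dataclass
class ThresholdClassifier:
    """A single learned cutoff on a 1-D score.

    ``cutoff`` is the midpoint between two adjacent observed training
    values; a score exactly at the cutoff goes to the "<= cutoff" side.
    When the association gate fails the model is degenerate: it
    predicts its training majority class for every input.
    """

    feature: str
    cutoff: float | None
    direction: str
    p_value: float
    degenerate: bool = False
    majority_class: bool = False
    min_leaf: int = 3
    alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0

    def predict(self, scores: pd.Series) -> pd.Series:
        """Predict responder (True) / non-responder (False) labels."""
        if scores.isna().any():
            bad = list(scores.index[scores.isna()])
            raise DataError(f"missing scores for samples: {bad}")
        if self.degenerate or self.cutoff is None:
            return pd.Series(self.majority_class, index=scores.index, dtype=bool)
        high = scores > self.cutoff  # ties at the cutoff go to the low side
        if self.direction == GREATER:
            return high
        return ~high

    def to_json(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ThresholdClassifier":
        with open(path) as fh:
            return cls(**json.load(fh))


def _permutation_p(
    scores: np.ndarray, labels: np.ndarray, n_perm: int, seed: int, exact_max_n: int = 12
) -> float:
    """Two-sided permutation p for the linear statistic sum(score*label).

    Exact enumeration over label placements when n <= exact_max_n,
    otherwise Monte-Carlo with ``n_perm`` draws (the observed statistic
    is counted once).
    """
    n = len(scores)
    n1 = int(labels.sum())
    obs = float(scores[labels].sum())
    center = n1 * scores.mean()
    t_obs = abs(obs - center)
    if n <= exact_max_n:
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            t = abs(scores[list(idx)].sum() - center)
            count += t >= t_obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    draws = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    t = np.abs(scores[draws].sum(axis=1) - center)
    count = 1 + int((t >= t_obs - 1e-12).sum())  # observed counted once
    return count / (n_perm + 1)


def fit_threshold_classifier(
    scores: pd.Series,
    labels: pd.Series,
    feature: str = "score",
    min_leaf: int = 3,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> ThresholdClassifier:
    """Fit a depth-1 conditional-inference threshold classifier.

    ``labels`` is boolean (True = responder).  The global association
    gate is a permutation test; only if p < alpha is a split placed,
    at the admissible midpoint maximizing the standardized two-sample
    statistic (each leaf >= ``min_leaf``).  Otherwise a degenerate
    majority-class model is returned.
    """
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise DataError("labels missing for some scored samples")
    y = labels.to_numpy(dtype=bool)
    s = scores.to_numpy(dtype=float)
    n = len(s)
    if n < 2 * min_leaf:
        raise DataError(f"need at least {2 * min_leaf} samples")
    if y.all() or not y.any():
        raise DataError("both classes must be present")

    p = _permutation_p(s, y, n_perm=n_perm, seed=seed)
    majority = bool(y.mean() > 0.5)
    if p >= alpha:
        return ThresholdClassifier(
            feature=feature,
            cutoff=None,
            direction=GREATER,
            p_value=p,
            degenerate=True,
            majority_class=majority,
            min_leaf=min_leaf,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
        )

    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order].astype(float)
    ybar = y_sorted.mean()
    ssy = ((y_sorted - ybar) ** 2).sum()
    best_stat, best_cut = -np.inf, None
    csum = np.cumsum(y_sorted)
    for i in range(min_leaf - 1, n - min_leaf):
        if s_sorted[i + 1] <= s_sorted[i]:
            continue  # not a valid midpoint between distinct values
        n_l = i + 1
        n_r = n - n_l
        t = csum[i]
        mu = n_l * ybar
        var = (n_l * n_r) / (n * (n - 1)) * ssy
        stat = abs(t - mu) / math.sqrt(var) if var > 0 else 0.0
        if stat > best_stat + 1e-12:
            best_stat = stat
            best_cut = 0.5 * (s_sorted[i] + s_sorted[i + 1])
    if best_cut is None:
        # all admissible midpoints tied / absent: degenerate fallback
        return ThresholdClassifier(
            feature=feature,
            cutoff=None,
            direction=GREATER,
            p_value=p,
            degenerate=True,
            majority_class=majority,
            min_leaf=min_leaf,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
        )
    high = s > best_cut
    rate_high = y[high].mean() if high.any() else 0.0
    rate_low = y[~high].mean() if (~high).any() else 0.0
    direction = GREATER if rate_high >= rate_low else LESSER
    return ThresholdClassifier(
        feature=feature,
        cutoff=float(best_cut),
        direction=direction,
        p_value=p,
        degenerate=False,
        majority_class=majority,
        min_leaf=min_leaf,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )


def classification_metrics(pred: pd.Series, truth: pd.Series) -> dict:
    """Accuracy, Matthews correlation and F1 with explicit N/A handling.

    MCC is reported as None (rendered "N/A") when any row or column
    marginal of the confusion matrix is zero — e.g. a degenerate
    single-class predictor.  F1 is None when there are no positives or
    precision + recall = 0.
    """
    truth = truth.reindex(pred.index)
    if truth.isna().any():
        raise DataError("truth labels missing for some predictions")
    if len(pred) == 0:
        raise DataError("empty input")
    p = pred.to_numpy(dtype=bool)
    t = truth.to_numpy(dtype=bool)
    tp = int((p & t).sum())
    tn = int((~p & ~t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    n = tp + tn + fp + fn
    accuracy = (tp + tn) / n
    marginals = [tp + fp, tn + fn, tp + fn, tn + fp]
    if any(m == 0 for m in marginals):
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
    if (tp + fn) == 0 or (tp + fp) == 0:
        f1 = None
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = None if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "mcc": mcc, "f1": f1}


def format_metric(value: float | None, pct: bool = False) -> str:
    if value is None:
        return "N/A"
    return f"{100 * value:.1f}%" if pct else f"{value:.3f}"


@dataclass
class SubtypeCall:
    """Nearest-centroid subtype call with indeterminate provenance."""

    sample_id: str
    correlations: dict[str, float]
    call: str
    margin: float
    rescue_source: str = "none"  # none | network_classifier
    reason: str = ""


def call_subtype(
    sample: pd.Series,
    centroids: CentroidModel,
    margin_threshold: float = 0.1,
) -> SubtypeCall:
    """Call the subtype whose centroid the sample rank-correlates with most.

    Spearman correlation (average ranks) against each centroid over
    the centroid gene list; the call is the argmax unless the top-two
    margin falls below ``margin_threshold``, in which case the call is
    INDETERMINATE.  A constant sample has undefined correlations and
    is INDETERMINATE with a reason code.
    """
    missing = [g for g in centroids.gene_ids if g not in sample.index]
    if missing:
        raise DataError(f"sample missing centroid genes: {missing[:10]}")
    x = sample.reindex(centroids.gene_ids).to_numpy(dtype=float)
    name = str(sample.name) if sample.name is not None else "sample"
    if np.all(x == x[0]):
        return SubtypeCall(
            sample_id=name,
            correlations={s: float("nan") for s in centroids.subtypes},
            call=INDETERMINATE,
            margin=float("nan"),
            reason="constant_sample",
        )
    corrs = {}
    for s in centroids.subtypes:
        rho = spearmanr(x, centroids.profiles[s].to_numpy()).statistic
        corrs[s] = float(rho)
    ranked = sorted(corrs.items(), key=lambda kv: (-kv[1], kv[0]))
    margin = ranked[0][1] - ranked[1][1]
    if margin < margin_threshold:
        return SubtypeCall(name, corrs, INDETERMINATE, margin, reason="low_margin")
    return SubtypeCall(name, corrs, ranked[0][0], margin)


def rescue_indeterminate(
    calls: list[SubtypeCall],
    predicted_response: pd.Series,
    good_subtype: str = "BLIA",
    poor_subtype: str = "BLIS",
) -> list[SubtypeCall]:
    """Resolve INDETERMINATE calls with a response predictor.

    Predicted responders become the good-prognosis subtype, predicted
    non-responders the poor-prognosis one; determinate calls pass
    through untouched.  A prediction must exist for every
    indeterminate sample.
    """
    out = []
    for c in calls:
        if c.call != INDETERMINATE:
            out.append(c)
            continue
        if c.sample_id not in predicted_response.index or pd.isna(
            predicted_response[c.sample_id]
        ):
            raise DataError(f"no response prediction for indeterminate sample {c.sample_id}")
        resp = bool(predicted_response[c.sample_id])
        out.append(
            SubtypeCall(
                sample_id=c.sample_id,
                correlations=c.correlations,
                call=good_subtype if resp else poor_subtype,
                margin=c.margin,
                rescue_source="network_classifier",
                reason=c.reason,
            )
        )
    return out


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "call": c.call,
            "margin": c.margin,
            "rescue_source": c.rescue_source,
            **{f"rho_{s}": v for s, v in c.correlations.items()},
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
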