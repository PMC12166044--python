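"""Differential testing of expression and network features.

Group contrasts (responder vs non-responder, or Bx1 vs Bx2) are
tested feature-by-feature with an empirical-Bayes moderated t: the
per-feature residual variances are shrunk toward a common prior (or an
abundance-trend prior) whose location and degrees of freedom are
estimated by moment matching on log-variances, exactly in the spirit
of the standard linear-model moderation used for microarray-scale
data.  Benjamini–Hochberg adjustment is applied across features.

Paired biopsy deltas (Bx2 - Bx1 per patient) and the sector
partition of the (expression t, network t) plane round out the
module-level "re-wiring vs expression" interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import ClinicalTable, DataError

__all__ = [
    "tmm_factors",
    "moderated_t",
    "paired_delta",
    "sector_assign",
]


# ---------------------------------------------------------------------------
# TMM normalization factors
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors per sample.

    M-values (log2 fold changes of within-library proportions) against
    a reference sample (default: highest library size) are trimmed by
    ``trim_m`` on M and ``trim_a`` on A (average abundance), weighted
    by inverse asymptotic binomial variances, and the weighted mean M
    gives the log2 factor.  Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise DataError("TMM needs at least 2 samples")
    if (counts < 0).any().any():
        raise DataError("counts must be nonnegative")
    counts = counts.loc[counts.sum(axis=1) > 0]
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise DataError("library sizes must be positive")
    ref = reference if reference is not None else lib.idxmax()
    yr = counts[ref].to_numpy(dtype=float)
    nr = float(lib[ref])
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        ys = counts[s].to_numpy(dtype=float)
        ns = float(lib[s])
        ok = (ys > 0) & (yr > 0)
        y1, y2 = ys[ok], yr[ok]
        m = np.log2((y1 / ns) / (y2 / nr))
        a = 0.5 * np.log2((y1 / ns) * (y2 / nr))
        w = (ns - y1) / (ns * y1) + (nr - y2) / (nr * y2)
        keep = np.ones(len(m), dtype=bool)
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep &= (m >= lo_m) & (m <= hi_m)
        keep &= (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            factors[s] = 1.0
            continue
        with np.errstate(divide="ignore"):
            inv_w = 1.0 / w[keep]
        f = (m[keep] * inv_w).sum() / inv_w.sum()
        factors[s] = float(2.0**f)
    fac = pd.Series(factors).reindex(counts.columns)
    fac /= np.exp(np.log(fac).mean())  # geometric mean 1
    fac.name = "tmm_factor"
    return fac


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y > 0."""
    if x <= 0:
        return np.inf
    # polygamma(1, y) is decreasing from +inf to 0
    lo, hi = 1e-8, 1e8
    f = lambda y: polygamma(1, y) - x
    if f(lo) < 0:
        return lo
    if f(hi) > 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-10, rtol=1e-12)


def _fit_f_dist(s2: np.ndarray, df: float, covariate: np.ndarray | None = None):
    """Moment-match a scaled-F prior to observed variances.

    Returns (prior_df, prior_s2 per feature).  With ``covariate`` the
    prior location follows a lowess trend of log-variance against it.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    if covariate is not None:
        cov = covariate[ok]
        fit = lowess(e, cov, frac=0.5, return_sorted=False)
        emean_all = np.interp(covariate, np.sort(cov), fit[np.argsort(cov)])
        resid = e - fit
    else:
        emean = e.mean()
        emean_all = np.full(len(s2), emean)
        resid = e - emean
    evar = resid.var(ddof=1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02_log = emean_all + digamma(d0 / 2.0) - np.log(d0 / 2.0)
    else:
        d0 = np.inf
        s02_log = emean_all
    return d0, np.exp(s02_log)


@dataclass
class ModeratedResult:
    table: pd.DataFrame
    prior_df: float


def moderated_t(
    matrix: pd.DataFrame,
    groups: pd.Series | None = None,
    trend: bool = False,
    paired_ids: pd.Series | None = None,
    prior_df: float | None = None,
    feature_type: str = "expression",
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-test per feature (row).

    Unpaired mode compares the two groups of ``groups`` (boolean; True
    minus False group difference).  Paired mode takes ``paired_ids``
    (sample -> pair id): within-pair differences (True-group column
    minus False-group column) are tested against zero.  Residual
    variances are shrunk toward the moment-matched prior; ``prior_df``
    overrides the estimated prior degrees of freedom (0 recovers the
    ordinary t-test exactly).  Rows with undefined (NaN) values are
    excluded with a logged count.

    Returns a DataFrame with effect, t, p, fdr (Benjamini–Hochberg)
    and feature_type, sorted as input.
    """
    x = matrix.copy()
    bad = x.isna().any(axis=1)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} feature(s) with undefined values")
        x = x.loc[~bad]
    if x.empty:
        raise DataError("no testable features")

    if paired_ids is not None:
        if groups is None:
            raise DataError("paired mode requires groups to orient the difference")
        groups = groups.reindex(x.columns)
        paired_ids = paired_ids.reindex(x.columns)
        pairs = {}
        for s in x.columns:
            pairs.setdefault(paired_ids[s], {})[bool(groups[s])] = s
        complete = [p for p, d in pairs.items() if len(d) == 2]
        if len(complete) < 2:
            raise DataError("need at least 2 complete pairs")
        diffs = pd.DataFrame(
            {p: x[pairs[p][True]] - x[pairs[p][False]] for p in complete}
        )
        n = diffs.shape[1]
        effect = diffs.mean(axis=1).to_numpy()
        s2 = diffs.var(axis=1, ddof=1).to_numpy()
        df = n - 1
        stderr_unit = 1.0 / np.sqrt(n)
    else:
        if groups is None:
            raise DataError("groups are required")
        groups = groups.reindex(x.columns)
        if groups.isna().any():
            raise DataError("group labels missing for some samples")
        g = groups.to_numpy(dtype=bool)
        n1, n0 = int(g.sum()), int((~g).sum())
        if n1 < 2 or n0 < 2:
            raise DataError("both groups need at least 2 samples")
        x1 = x.loc[:, g].to_numpy()
        x0 = x.loc[:, ~g].to_numpy()
        effect = x1.mean(axis=1) - x0.mean(axis=1)
        ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (x0 - x0.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        df = n1 + n0 - 2
        s2 = ss / df
        stderr_unit = np.sqrt(1.0 / n1 + 1.0 / n0)
    if df < 1:
        raise DataError("zero residual degrees of freedom")

    covariate = x.mean(axis=1).to_numpy() if trend else None
    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, df, covariate)
    elif prior_df == 0:
        d0, s02 = 0.0, np.ones_like(s2)
    else:
        d0 = float(prior_df)
        _, s02 = _fit_f_dist(s2, df, covariate)

    if np.isinf(d0):
        post_s2 = s02
        total_df = np.inf
    else:
        post_s2 = (d0 * s02 + df * s2) / (d0 + df)
        total_df = df + d0
    se = np.sqrt(post_s2) * stderr_unit
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = effect / se
    if np.isinf(total_df):
        from scipy.stats import norm as _norm

        p = 2.0 * _norm.sf(np.abs(tstat))
    else:
        p = 2.0 * t_dist.sf(np.abs(tstat), total_df)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "effect": effect,
            "t": tstat,
            "p": p,
            "fdr": fdr,
            "feature_type": feature_type,
        },
        index=x.index,
    )


def paired_delta(matrix: pd.DataFrame, clinical: ClinicalTable) -> pd.DataFrame:
    """Per-patient Bx2 - Bx1 difference matrix.

    Only complete pairs are kept; unpaired samples are dropped with a
    warning.  Columns are patient ids.
    """
    t = clinical.table
    if t.duplicated(["patient_id", "biopsy"]).any():
        raise DataError("duplicate biopsy per patient")
    out = {}
    dropped = 0
    for pid, grp in t.groupby("patient_id"):
        by = grp.set_index("biopsy")["sample_id"]
        if "Bx1" in by.index and "Bx2" in by.index and by["Bx1"] in matrix.columns and by["Bx2"] in matrix.columns:
            out[pid] = matrix[by["Bx2"]] - matrix[by["Bx1"]]
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropping {dropped} patient(s) without complete pairs")
    if not out:
        raise DataError("no complete biopsy pairs")
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# sector plots
# ---------------------------------------------------------------------------

def sector_assign(
    t_expr: pd.Series,
    t_net: pd.Series,
    boundary_angle: float = 30.0,
) -> pd.DataFrame:
    """Partition genes into six sectors of the (t_expr, t_net) plane.

    Sectors 2 and 5 are the wedges within ``boundary_angle`` degrees
    of the +t_net and -t_net axes (differences attributable to wiring
    alone); sectors 1/3 flank sector 2 and 6/4 flank sector 5 (mixed
    expression + wiring).  Boundary ties go to the lower-numbered
    sector; the origin is unassigned (sector 0).
    """
    if not 0 < boundary_angle < 90:
        raise DataError("boundary_angle must lie in (0, 90)")
    te = t_expr.to_numpy(dtype=float)
    tn = t_net.reindex(t_expr.index).to_numpy(dtype=float)
    if np.isnan(te).any() or np.isnan(tn).any():
        raise DataError("sector assignment requires finite t statistics")
    theta = np.degrees(np.arctan2(tn, te))  # (-180, 180]
    b = boundary_angle
    sector = np.zeros(len(te), dtype=int)
    upper2 = (theta > 90 - b) & (theta <= 90 + b)
    sector[upper2] = 2
    sector[(theta >= 0) & (theta <= 90 - b)] = 1
    sector[(theta > 90 + b) | np.isclose(theta, 180.0)] = 3
    lower5 = (theta > -90 - b) & (theta <= -90 + b)
    sector[lower5] = 5
    sector[(theta > -90 + b) & (theta < 0)] = 6
    sector[(theta < 0) & (theta <= -90 - b)] = 4
    origin = (te == 0) & (tn == 0)
    sector[origin] = 0
    # negative-axis direction theta == 180 handled above as sector 3
    return pd.DataFrame(
        {"sector": sector, "t_expr": te, "t_net": tn, "theta_deg": theta},
        index=t_expr.index,
    )
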