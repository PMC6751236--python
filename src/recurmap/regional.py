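"""Region-level comparison of failure vs responder uptake.

Six first-order histogram features (min, max, mean, population variance,
Fisher skewness, excess kurtosis) summarize the pre-treatment SUV distribution
inside each region.  Paired differences across the cohort are tested with the
Wilcoxon signed-rank test, exact (full sign enumeration with mid-ranks for
ties) up to n = 15 informative pairs and a continuity-corrected normal
approximation beyond.  Fleiss's kappa quantifies agreement between several
raters assigning registrations to accept/reject categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .core import ImageVolume, Mask

__all__ = [
    "HistogramFeatures",
    "PairedTestResult",
    "histogram_features",
    "wilcoxon_signed_rank",
    "fleiss_kappa",
    "compare_regions",
    "HISTOGRAM_FEATURE_NAMES",
]

HISTOGRAM_FEATURE_NAMES = ("minimum", "maximum", "mean", "variance", "skewness", "kurtosis")

EXACT_MAX_N = 15  # full 2^n sign enumeration up to here


@dataclass(frozen=True)
class HistogramFeatures:
    minimum: float
    maximum: float
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    defined: bool = True  # False when the region is a single voxel

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.minimum, self.maximum, self.mean, self.variance, self.skewness, self.kurtosis]
        )


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    exact: bool


def histogram_features(pet: ImageVolume, region: Mask) -> HistogramFeatures:
    """First-order SUV statistics inside a region.

    Population variance, Fisher (moment) skewness and excess kurtosis; a
    single-voxel region has zero variance and undefined higher moments.
    """
    if region.count == 0:
        raise ValueError("histogram features undefined for an empty region")
    v = pet.values[region.membership]
    if v.size == 1:
        return HistogramFeatures(float(v[0]), float(v[0]), float(v[0]), 0.0,
                                 float("nan"), float("nan"), defined=False)
    mean = float(v.mean())
    var = float(v.var())  # population (ddof=0)
    if var == 0:
        skew = kurt = float("nan")
        defined = False
    else:
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, fisher=True, bias=True))
        defined = True
    return HistogramFeatures(float(v.min()), float(v.max()), mean, var, skew, kurt, defined)


def _signed_ranks(diff: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(np.abs(diff))  # mid-ranks for ties
    return ranks


def wilcoxon_signed_rank(paired_a: np.ndarray, paired_b: np.ndarray) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    The statistic is W+ = sum of ranks of the positive differences a - b
    (zero differences dropped, mid-ranks for ties).  For n <= 15 informative
    pairs the p value is exact, from full enumeration of the 2^n equiprobable
    sign assignments conditional on the observed |differences|; beyond that a
    normal approximation with continuity and tie corrections is used.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired samples must be 1D, equal length >= 2")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        raise ValueError("degenerate pairing: all differences are zero")
    ranks = _signed_ranks(diff)
    w_plus = float(ranks[diff > 0].sum())
    total = float(ranks.sum())

    if n <= EXACT_MAX_N:
        # null distribution of W+ conditional on the observed rank values
        m = 1 << n
        signs = (np.arange(m)[:, None] >> np.arange(n)) & 1
        w = signs @ ranks
        count_le = int((w <= w_plus + 1e-9).sum())
        count_ge = int((w >= w_plus - 1e-9).sum())
        p = min(1.0, 2.0 * min(count_le, count_ge) / m)
        return PairedTestResult(w_plus, p, int(n), exact=True)

    mean = total / 2.0
    # variance with tie correction: sum r_i^2 / 4
    var = float((ranks**2).sum()) / 4.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return PairedTestResult(w_plus, p, int(n), exact=False)


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss's kappa from an items x categories count table.

    Every item must be rated by the same number (>= 2) of raters.  Undefined
    (raises) when expected agreement is 1, i.e. all raters used one category
    for every item.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("ratings must be an items x categories table")
    row_sums = table.sum(axis=1)
    if not np.all(row_sums == row_sums[0]) or row_sums[0] < 2:
        raise ValueError("every item must be rated by the same number (>= 2) of raters")
    p_cat = table.sum(axis=0) / table.sum()
    if np.isclose((p_cat**2).sum(), 1.0):
        raise ValueError("kappa undefined: all ratings fall in a single category")
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def compare_regions(
    cohort: list[tuple[HistogramFeatures, HistogramFeatures]],
) -> pd.DataFrame:
    """Paired failure-vs-responder comparison of the six histogram features.

    ``cohort`` holds one (failure, responder) feature pair per patient.
    Returns one row per feature with cohort means +- SD per region and the
    Wilcoxon signed-rank p value (no multiple-testing correction across the
    six features; the tests are reported as-is).
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 patients for a paired comparison")
    fail = np.vstack([f.as_array() for f, _ in cohort])
    resp = np.vstack([r.as_array() for _, r in cohort])
    rows = []
    for j, name in enumerate(HISTOGRAM_FEATURE_NAMES):
        fa, ra = fail[:, j], resp[:, j]
        ok = np.isfinite(fa) & np.isfinite(ra)
        fa, ra = fa[ok], ra[ok]
        row = {
            "feature": name,
            "failure_mean": float(np.mean(fa)),
            "failure_sd": float(np.std(fa, ddof=1)) if fa.size > 1 else float("nan"),
            "responder_mean": float(np.mean(ra)),
            "responder_sd": float(np.std(ra, ddof=1)) if ra.size > 1 else float("nan"),
            "n_pairs": int(fa.size),
        }
        try:
            res = wilcoxon_signed_rank(fa, ra)
            row["statistic"] = res.statistic
            row["p_value"] = res.p_value
            row["degenerate"] = False
        except ValueError:
            row["statistic"] = float("nan")
            row["p_value"] = float("nan")
            row["degenerate"] = True
        rows.append(row)
    return pd.DataFrame(rows)
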