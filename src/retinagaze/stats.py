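"""Statistical comparisons: rank tests, inter-grader agreement, normality,
and accuracy-covariate correlation.

Group comparisons of gaze metrics use the Mann-Whitney U test (the metric
distributions are far from normal); inter-grader agreement on ordinal
severity grades uses Krippendorff's alpha, which handles missing ratings
(not every grader saw every image) and an ordinal distance metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney",
    "krippendorff_alpha",
    "normality_test",
    "accuracy_covariate_corr",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test; returns the U statistic of ``a``.

    U_a counts pairs where a beats b plus half-ties, so U_a + U_b always
    equals n_a * n_b. Exact enumeration for small tie-free samples, normal
    approximation with tie correction otherwise (scipy's auto policy).
    Identical constant samples are a degenerate case with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    u_a = float((a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum())
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult(statistic=u_a, pvalue=1.0)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def krippendorff_alpha(
    ratings: np.ndarray, level: str = "ordinal"
) -> float:
    """Krippendorff's alpha for a units x raters matrix with missing entries.

    Parameters
    ----------
    ratings
        Shape ``(n_units, n_raters)`` of numeric category codes with NaN
        for missing ratings. Units with fewer than two ratings contribute
        nothing (pairable-value weighting).
    level
        ``"nominal"`` (0/1 disagreement) or ``"ordinal"`` (squared
        cumulative-margin distance, appropriate for a graded severity
        scale).

    Returns ``1 - D_o / D_e`` from the coincidence matrix; raises when no
    unit has two pairable values or every value is identical (expected
    disagreement zero -> alpha undefined by convention unless observed
    disagreement is also zero, in which case 1.0 is returned).
    """
    if level not in ("nominal", "ordinal"):
        raise ValueError("level must be 'nominal' or 'ordinal'")
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValueError("ratings must be (n_units, n_raters) with >= 2 raters")

    cats = np.unique(R[~np.isnan(R)])
    if cats.size == 0:
        raise ValueError("no ratings present")
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)

    # Coincidence matrix: every ordered pair of values within a unit
    # contributes 1/(m_u - 1), m_u = number of values in the unit.
    o = np.zeros((k, k))
    for row in R:
        vals = row[~np.isnan(row)]
        m = len(vals)
        if m < 2:
            continue
        w = 1.0 / (m - 1)
        for i in range(m):
            for j in range(m):
                if i != j:
                    o[index[vals[i]], index[vals[j]]] += w
    n_c = o.sum(axis=1)
    n = n_c.sum()
    if n == 0:
        raise ValueError("no pairable values: alpha undefined")

    if level == "nominal":
        delta = 1.0 - np.eye(k)
    else:
        # ordinal distance: squared difference of cumulative margins,
        # delta_ck = (sum_{g=c..k} n_g - (n_c + n_k)/2)^2
        delta = np.zeros((k, k))
        for c in range(k):
            for d in range(c + 1, k):
                s = n_c[c : d + 1].sum() - (n_c[c] + n_c[d]) / 2.0
                delta[c, d] = delta[d, c] = s * s

    d_o = (o * delta).sum() / n
    d_e = (np.outer(n_c, n_c) * delta).sum() / (n * (n - 1))
    if d_e == 0:
        if d_o == 0:
            return 1.0
        raise ValueError("expected disagreement is zero: alpha undefined")
    return float(1.0 - d_o / d_e)


def normality_test(sample) -> TestResult:
    """Shapiro-Wilk normality test (W, p); requires 3 <= n <= 5000 and a
    non-constant sample."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test degenerate")
    res = sps.shapiro(x)
    return TestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def accuracy_covariate_corr(per_participant_accuracy, covariate) -> TestResult:
    """Squared Pearson correlation (r^2) between per-participant accuracy
    and a covariate such as age or years of experience, with the two-sided
    p-value of the linear association."""
    a = np.asarray(per_participant_accuracy, dtype=float)
    c = np.asarray(covariate, dtype=float)
    if len(a) != len(c) or len(a) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(c) == 0 or np.ptp(a) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = sps.pearsonr(a, c)
    return TestResult(statistic=float(r * r), pvalue=float(p))
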