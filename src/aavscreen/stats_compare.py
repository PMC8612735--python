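"""Inferential comparison of variants across samples.

The analysis is deliberately nonparametric: a Shapiro-Wilk screen (advisory
only), a Friedman omnibus test across variants with samples as blocks, and
focal one-sided Wilcoxon signed-rank tests of a chosen variant against
every other, Benjamini-Hochberg corrected within that family.

The Friedman statistic and the exact signed-rank null are implemented here
(mid-ranks, tie correction, dynamic-programming enumeration of the exact
sign-flip distribution); scipy's versions serve only as cross-checks in the
test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata, shapiro
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

EXACT_N_MAX = 25


def check_normality(values) -> dict[str, float]:
    """Shapiro-Wilk test; advisory only, the pipeline stays nonparametric."""
    x = np.asarray(values, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("constant input: variance undefined")
    W, p = shapiro(x)
    return {"W": float(W), "p": float(p)}


def sample_by_variant(metrics: pd.DataFrame, value: str = "pct_infected",
                      cell_type: str = "Total") -> pd.DataFrame:
    """Reshape a MetricsTable to samples x variants for one cell type."""
    sub = metrics[metrics["cell_type"] == cell_type]
    return sub.pivot(index="sample_id", columns="variant_id", values=value)


def friedman_test(m: pd.DataFrame) -> dict[str, float]:
    """Friedman's rank test across variants with samples as blocks.

    Values are mid-ranked within each sample; the chi-square statistic uses
    the standard tie correction. Requires a complete matrix: missing cells
    are an error, never imputed.
    """
    arr = np.asarray(m, dtype=float)
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 samples and >= 2 variants")
    if np.isnan(arr).any():
        raise ValidationError("missing cells in sample x variant matrix")
    ranks = np.apply_along_axis(rankdata, 1, arr)
    Rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(Rj ** 2) - 3.0 * n * (k + 1)
    # tie correction: C = 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_sum = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts ** 3 - counts).sum())
    C = 1.0 - tie_sum / (n * k * (k ** 2 - 1))
    if C <= 0:  # all values tied in every sample
        return {"chi2": 0.0, "df": k - 1, "p": 1.0}
    stat /= C
    df = k - 1
    return {"chi2": float(stat), "df": df, "p": float(chi2.sf(stat, df))}


def _exact_signed_rank_p_greater(diffs: np.ndarray) -> float:
    """P(W+ >= observed) by exact enumeration of all sign assignments.

    Uses a subset-sum dynamic program over twice the mid-ranks (integers),
    equivalent to enumerating all 2^n sign patterns.
    """
    ranks = rankdata(np.abs(diffs))
    scaled = np.round(2 * ranks).astype(int)  # midranks *2 are integers
    w_obs = int(round(float(scaled[diffs > 0].sum())))
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    n_ge = int(sum(counts[w_obs:]))
    return n_ge / (2 ** len(diffs))


def signed_rank_p(x: np.ndarray, y: np.ndarray,
                  alternative: str = "greater") -> tuple[float, bool]:
    """One-sided paired Wilcoxon signed-rank p-value of x vs y.

    Zero differences are dropped (standard convention). Exact enumeration
    of the sign-flip null for n <= 25 non-zero pairs; normal approximation
    with tie correction and continuity correction above. Returns (p,
    all_zero_flag); when every paired difference is zero the comparison is
    uninformative and p = 1 with the flag set.
    """
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if alternative == "less":
        d = -d
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0, True
    if n <= EXACT_N_MAX:
        return float(_exact_signed_rank_p_greater(d)), False
    ranks = rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts ** 3 - tie_counts)).sum()) / 48.0
    z = (w - mu - 0.5) / np.sqrt(var)
    return float(norm.sf(z)), False


def focal_wilcoxon_bh(m: pd.DataFrame, focal: str,
                      alternative: str = "greater") -> pd.DataFrame:
    """Focal variant vs each other variant, paired across samples, with BH.

    One row per non-focal variant: raw one-sided signed-rank p of
    focal > other (by default) and the Benjamini-Hochberg adjusted p over
    this family of comparisons. ``all_zero`` flags comparisons where every
    paired difference was zero (reported with p = 1).
    """
    if focal not in m.columns:
        raise ValidationError(f"focal variant {focal!r} not in matrix columns")
    arr = np.asarray(m, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("missing cells in sample x variant matrix")
    others = [c for c in m.columns if c != focal]
    if not others:
        raise ValidationError("no comparison variants")
    raws, flags = [], []
    for other in others:
        p, flag = signed_rank_p(m[focal].to_numpy(), m[other].to_numpy(),
                                alternative=alternative)
        raws.append(p)
        flags.append(flag)
    bh = multipletests(raws, method="fdr_bh")[1]
    return pd.DataFrame({
        "variant_id": others,
        "raw_p": raws,
        "bh_p": bh,
        "all_zero": flags,
    })
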