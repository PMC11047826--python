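"""Statistical companion analyses.

Group comparisons use the pooled-variance (Student) two-sample t-test,
available both from raw samples and from published summary statistics
(mean, SD, n per group). Questionnaire contingency tables are compared
with the Pearson chi-square test; a Mann-Whitney U test is provided as
the nonparametric fallback. Feature-vs-electrodiagnostic association is a
pairwise Pearson correlation matrix in which coefficients below 0.100 in
magnitude are masked (shown as empty cells), mirroring the reporting
convention for such tables. No multiple-testing correction is applied by
default; Benjamini-Hochberg adjustment is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset

#: Nerves, fiber types and electrode-site codes used in the
#: electrodiagnostic (nerve conduction) tables.
NERVES = ("medianus", "ulnaris", "peroneus", "tibialis", "suralis")
SIDES = ("left", "right")
FIBERS = ("motor", "sensory")
SITE_CODES = ("ra", "pr", "sa", "se", "ps", "rp")


@dataclass
class TestResult:
    statistic: float
    df: float
    pvalue: float


def two_sample_ttest(
    mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None,
    sample1=None, sample2=None,
) -> TestResult:
    """Pooled-variance two-sample t-test, from raw samples or summaries.

    Pass either both raw ``sample1``/``sample2`` vectors, or the six
    summary statistics (mean, SD, n per group). The pooled form assumes
    equal group variances; its degrees of freedom are ``n1 + n2 - 2``.
    """
    if sample1 is not None or sample2 is not None:
        if sample1 is None or sample2 is None:
            raise ValueError("both raw samples are required")
        a = np.asarray(sample1, dtype=float)
        b = np.asarray(sample2, dtype=float)
        mean1, sd1, n1 = a.mean(), a.std(ddof=1), a.size
        mean2, sd2, n2 = b.mean(), b.std(ddof=1), b.size
    if None in (mean1, sd1, n1, mean2, sd2, n2):
        raise ValueError("provide raw samples or all six summary statistics")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0:
        if mean1 == mean2:
            return TestResult(0.0, float(df), 1.0)
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = (mean1 - mean2) / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p))


def chi_square_test(table) -> TestResult:
    """Pearson chi-square test of independence on an R x C count table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold nonnegative integer counts")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    for axis_name, sums in (("row", row_sums), ("column", col_sums)):
        zero = np.flatnonzero(sums == 0)
        if zero.size:
            raise ValueError(f"{axis_name}(s) {list(zero)} have zero total count")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(float(res[0]), float(res[2]), float(res[1]))


def mann_whitney_u(sample1, sample2) -> TestResult:
    """Mann-Whitney U (two-sided) with the normal/tie-corrected p-value.

    On heavily tied data (e.g. 0/1 scores) the tie correction shrinks the
    null variance; the test degrades gracefully rather than failing.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult(float(res.statistic), float("nan"), float(res.pvalue))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default report)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def correlation_matrix(
    features: CohortDataset | pd.DataFrame,
    edx: pd.DataFrame,
    mask_threshold: float = 0.100,
    include_label: bool = True,
) -> pd.DataFrame:
    """Pearson correlations of EDx parameters (rows) vs features (columns).

    Pairs are formed per cell from pairwise-complete observations (at
    least 3 required). Coefficients with magnitude below
    ``mask_threshold`` are masked to NaN and serialize as empty cells.
    With ``include_label`` the binary neuropathy indicator is the first
    column (its correlation with a continuous variable is the
    point-biserial coefficient, i.e. Pearson on a 0/1 coding). Constant
    columns yield masked cells with a warning.
    """
    if isinstance(features, CohortDataset):
        feat_df = features.X.copy()
        label = pd.Series(features.y, index=feat_df.index, name="DMN")
    else:
        feat_df = features.copy()
        label = None
    if include_label and label is not None:
        feat_df.insert(0, "DMN", label)
    edx = edx.select_dtypes(include=[np.number])
    if len(edx) != len(feat_df):
        raise ValueError("feature and EDx tables must describe the same subjects, row-aligned")

    out = pd.DataFrame(index=edx.columns, columns=feat_df.columns, dtype=float)
    for row in edx.columns:
        for col in feat_df.columns:
            x = edx[row].to_numpy(dtype=float)
            y = feat_df[col].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                out.loc[row, col] = np.nan
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                import warnings

                warnings.warn(f"constant column in pair ({row}, {col}); cell masked")
                out.loc[row, col] = np.nan
                continue
            r = float(stats.pearsonr(x[ok], y[ok]).statistic)
            out.loc[row, col] = r if abs(r) >= mask_threshold else np.nan
    return out


def write_correlation_csv(matrix: pd.DataFrame, path) -> None:
    """Serialize with empty cells for masked entries."""
    matrix.to_csv(path, na_rep="")
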