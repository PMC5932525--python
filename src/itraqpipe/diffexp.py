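"""Presence filtering and dual-criterion differential expression.

For every pairwise group comparison a protein must clear two independent
significance hurdles to be called differentially expressed:

1. a Welch two-sided t-test on the normalized intensities of the two
   groups (applied only to proteins whose pooled, group-mean-centered
   residuals pass a Lilliefors-corrected Kolmogorov-Smirnov normality
   screen), and
2. a magnitude test on the log2 expression ratio: per comparison the
   ratio of group means is log2-transformed and centered on the
   comparison-wide mean, a Gaussian with that empirical spread is fitted
   to the centered values, and the two-sided tail probability of each
   protein's |centered l2r| is its magnitude p-value.

Both p-values must fall below alpha (default 0.05).  No multiple-testing
correction is applied by default; Benjamini-Hochberg is available as an
opt-in flag.  Missing cells are excluded pairwise and never imputed.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .design import BatchDesign
from .synthdata import parse_comparison

log = logging.getLogger(__name__)

STATS_COLUMNS = (
    "t_p",
    "normal_flag",
    "ratio",
    "l2r",
    "l2r_centered",
    "l2r_p",
    "fold_change",
    "significant",
)


def min_present(group_size: int, threshold: float) -> int:
    """Smallest per-group observation count that clears the presence filter.

    With groups of 12 at the conventional 70 % threshold this is 9.
    """
    return math.ceil(threshold * group_size)


def presence_filter(
    matrix: pd.DataFrame,
    design: BatchDesign,
    threshold: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep proteins observed in >= ``threshold`` of samples of EVERY group.

    Returns the filtered matrix and the per-protein, per-group presence
    counts used for the decision.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"presence threshold must lie in (0, 1]: {threshold}")
    if matrix.empty:
        warnings.warn("presence_filter received an empty matrix", stacklevel=2)
        return matrix, pd.DataFrame(index=matrix.index, columns=design.groups)
    groups = design.sample_groups
    counts = matrix.notna().T.groupby(groups.reindex(matrix.columns)).sum().T
    counts = counts.loc[:, design.groups]
    sizes = design.group_sizes()
    required = {g: min_present(int(sizes[g]), threshold) for g in design.groups}
    keep = pd.Series(True, index=matrix.index)
    for g in design.groups:
        keep &= counts[g] >= required[g]
    log.info(
        "presence filter (threshold %.2f, required %s): retained %d of %d proteins",
        threshold, required, int(keep.sum()), len(keep),
    )
    return matrix.loc[keep], counts


def _group_values(
    matrix: pd.DataFrame, design: BatchDesign, group: str
) -> pd.DataFrame:
    samples = [s for s in matrix.columns if design.sample_groups[s] == group]
    return matrix.loc[:, samples]


def normality_screen(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> bool:
    """Lilliefors-corrected KS normality test on pooled residuals.

    Residuals are each group's observed values minus that group's mean,
    pooled across the two groups.  Returns True when normality is NOT
    rejected at ``alpha``.  Fewer than 3 observations in either group, or
    zero pooled spread, yields False (the protein cannot be screened).
    The Lilliefors correction is required because the Gaussian mean and
    sd are estimated from the same sample; the plain KS test would be
    anticonservative.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        return False
    resid = np.concatenate([a - a.mean(), b - b.mean()])
    if np.ptp(resid) == 0:
        return False
    _, p = lilliefors(resid, dist="norm", pvalmethod="table")
    return bool(p >= alpha)


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    NaN when either group has < 2 observations or both groups are
    constant (zero pooled variance makes the statistic undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # no within-group variance: undefined when means agree, else arbitrarily strong
        return float("nan") if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def ratio_stats(
    matrix: pd.DataFrame, design: BatchDesign, comparison: str | tuple[str, str]
) -> pd.DataFrame:
    """Per-protein ratio of group means, its log2, and the centered log2.

    ``ratio = mean(observed A) / mean(observed B)`` with A the
    first-named group; ``l2r = log2(ratio)``; ``l2r_centered`` subtracts
    the comparison-wide mean l2r so the centered values average zero.
    Proteins unobserved in a group, or with a zero group mean, are
    excluded from the comparison (NaN row, logged).
    """
    ga, gb = parse_comparison(comparison)
    mean_a = _group_values(matrix, design, ga).mean(axis=1)
    mean_b = _group_values(matrix, design, gb).mean(axis=1)
    valid = (mean_a > 0) & (mean_b > 0)
    n_bad = int((~valid).sum())
    if n_bad:
        log.info("%s: %d proteins excluded (unobserved or zero group mean)", comparison, n_bad)
    ratio = pd.Series(np.where(valid, mean_a / mean_b, np.nan), index=matrix.index)
    l2r = np.log2(ratio)
    out = pd.DataFrame({"ratio": ratio, "l2r": l2r})
    out["l2r_centered"] = l2r - l2r.mean()
    out.index.name = "protein_id"
    return out


def l2r_pvalue(l2r_centered: pd.Series | np.ndarray) -> pd.Series:
    """Magnitude-based p-value of centered log2 ratios.

    A Gaussian is fitted to the comparison's centered l2r distribution
    (mean 0 by construction, sd = sample sd over proteins); each
    protein's p-value is the two-sided tail probability of its
    |centered l2r| under that fit, hence monotone decreasing in the
    magnitude of change.
    """
    x = pd.Series(l2r_centered, dtype=float)
    obs = x.dropna()
    if len(obs) < 10:
        raise ValueError(
            f"need >= 10 proteins to estimate the l2r distribution, got {len(obs)}"
        )
    sd = float(obs.std(ddof=1))
    if sd == 0.0:
        warnings.warn("centered l2r values have zero spread; all magnitude p-values = 1")
        return pd.Series(np.where(x.isna(), np.nan, 1.0), index=x.index)
    p = 2.0 * stats.norm.sf(x.abs() / sd)
    return pd.Series(np.minimum(p, 1.0), index=x.index)


def fold_change(l2r):
    """Signed fold change: ``2**l2r`` if up, ``-2**(-l2r)`` if down.

    Magnitudes are always >= 1 and ``fold_change(0) == 1``, matching the
    reporting convention of proteomics ratio tables.
    """
    arr = np.asarray(l2r, dtype=float)
    fold = np.where(arr >= 0, np.exp2(arr), -np.exp2(-arr))
    if np.isscalar(l2r) or arr.ndim == 0:
        return float(fold)
    if isinstance(l2r, pd.Series):
        return pd.Series(fold, index=l2r.index)
    return fold


def select_differential(table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Dual significance criterion.

    A protein is differentially expressed iff its t-test p-value AND its
    magnitude-based l2r p-value are both below ``alpha`` and it passed
    the normality screen.  Missing p-values never qualify.
    """
    t_ok = table["t_p"] < alpha
    m_ok = table["l2r_p"] < alpha
    sig = t_ok.fillna(False) & m_ok.fillna(False) & table["normal_flag"].astype(bool)
    return sig.astype(bool)


def compare(
    matrix: pd.DataFrame,
    design: BatchDesign,
    comparison: str | tuple[str, str],
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Full per-protein statistics table for one pairwise comparison.

    Columns: ``t_p, normal_flag, ratio, l2r, l2r_centered, l2r_p,
    fold_change, significant`` (plus observation counts ``n_a, n_b``).
    Proteins failing the normality screen receive no t-test verdict
    (``t_p`` NaN) and can never be flagged significant.  With
    ``bh_correction`` both p-value families are Benjamini-Hochberg
    adjusted before thresholding (off by default).
    """
    ga, gb = parse_comparison(comparison)
    for g in (ga, gb):
        if g not in design.groups:
            raise ValueError(f"comparison group {g!r} not declared in the design")
    va = _group_values(matrix, design, ga).to_numpy(dtype=float)
    vb = _group_values(matrix, design, gb).to_numpy(dtype=float)

    out = ratio_stats(matrix, design, comparison)
    out["n_a"] = np.sum(~np.isnan(va), axis=1)
    out["n_b"] = np.sum(~np.isnan(vb), axis=1)

    normal = np.empty(len(out), dtype=bool)
    t_p = np.full(len(out), np.nan)
    for i in range(len(out)):
        normal[i] = normality_screen(va[i], vb[i], alpha=normality_alpha)
        if normal[i]:
            t_p[i] = welch_t(va[i], vb[i])
    out["normal_flag"] = normal
    out["t_p"] = t_p
    out["l2r_p"] = l2r_pvalue(out["l2r_centered"])
    out["fold_change"] = fold_change(out["l2r"])

    if bh_correction:
        for col in ("t_p", "l2r_p"):
            mask = out[col].notna()
            if mask.any():
                out.loc[mask, col] = multipletests(out.loc[mask, col], method="fdr_bh")[1]
    out["significant"] = select_differential(out, alpha=alpha)
    cols = ["n_a", "n_b", *STATS_COLUMNS]
    out = out.loc[:, cols]
    log.info(
        "%s: %d of %d proteins significant (alpha %.3g)",
        comparison, int(out["significant"].sum()), len(out), alpha,
    )
    return out


def run_comparisons(
    matrix: pd.DataFrame,
    design: BatchDesign,
    comparisons: Sequence[str],
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
    bh_correction: bool = False,
) -> Mapping[str, pd.DataFrame]:
    """``compare`` for every requested comparison, keyed by its label."""
    return {
        comp: compare(
            matrix, design, comp,
            alpha=alpha, normality_alpha=normality_alpha, bh_correction=bh_correction,
        )
        for comp in comparisons
    }


def volcano_table(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Centered l2r vs -log10 t-test p, for volcano-style inspection.

    Proteins without a t-test verdict (failed screen or degenerate test)
    are omitted.
    """
    keep = stats_table["t_p"].notna()
    out = pd.DataFrame(
        {
            "l2r_centered": stats_table.loc[keep, "l2r_centered"],
            "minus_log10_t_p": -np.log10(stats_table.loc[keep, "t_p"]),
        }
    )
    out.index.name = "protein_id"
    return out
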