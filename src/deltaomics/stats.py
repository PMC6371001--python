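"""Paired change testing: Wilcoxon signed-rank with per-class BH adjustment.

Within-subject changes (week6 - baseline) are tested per variable with the
two-sided Wilcoxon signed-rank test; multiple testing is corrected with
Benjamini-Hochberg independently within each class of variable.  For small
samples (<= 25 non-zero pairs) the exact null distribution of the positive
rank sum is enumerated (with mid-ranks for ties); beyond that a normal
approximation with tie and continuity corrections is used.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("deltaomics")

EXACT_LIMIT = 25


@dataclass
class PairedTestResult:
    feature: str
    n_pairs: int
    statistic: float       # W+ = sum of positive ranks
    p_raw: float
    p_adjusted: float = np.nan
    class_label: str = ""


def _exact_sf_counts(ranks: np.ndarray) -> np.ndarray:
    """Distribution of the positive rank sum over all sign assignments.

    Mid-ranks are multiples of 1/2, so doubled ranks are integers and the
    2^m equally likely sign vectors are enumerated by dynamic programming
    (subset-sum convolution).  Returns counts indexed by doubled rank sum.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank(before, after) -> tuple:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon convention).  Returns
    ``(W, p)`` where ``W`` is the positive rank sum of ``after - before``.
    All differences zero gives the defined result ``(0.0, 1.0)`` with a
    warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must have equal length")
    d = after - before
    d = d[~np.isnan(d)]
    d = d[d != 0]
    m = d.size
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1.0")
        return 0.0, 1.0
    if m < 4:
        raise ValueError(
            f"need >= 4 non-zero paired differences, got {m}")
    ranks = rankdata(np.abs(d))          # mid-ranks for ties
    w_pos = ranks[d > 0].sum()

    if m <= EXACT_LIMIT:
        counts = _exact_sf_counts(ranks)
        total = 2.0 ** m
        k = int(np.rint(2 * w_pos))
        p_low = counts[:k + 1].sum() / total
        p_high = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return float(w_pos), float(p)

    # normal approximation with tie and continuity corrections
    mean = m * (m + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / 48.0
    sd = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0 - tie_term)
    diff = w_pos - mean
    z = (diff - 0.5 * np.sign(diff)) / sd
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return float(w_pos), float(p)


def adjust_bh(p_values, class_labels=None) -> np.ndarray:
    """Benjamini-Hochberg step-up, applied independently within each class."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values.copy()
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if class_labels is None:
        class_labels = np.zeros(p_values.size)
    class_labels = np.asarray(class_labels)
    if class_labels.size != p_values.size:
        raise ValueError("class_labels length must match p_values")
    adjusted = np.empty_like(p_values)
    for cls in pd.unique(class_labels):
        mask = class_labels == cls
        adjusted[mask] = multipletests(p_values[mask], method="fdr_bh")[1]
    return adjusted


def paired_change_table(baseline, week6, alpha: float = 0.05) -> pd.DataFrame:
    """Test every feature of a block pair for within-subject change.

    ``baseline`` / ``week6`` are :class:`~deltaomics.blocks.OmicsBlock` with
    identical features; BH adjustment pools features by the block class.
    Returns a table with columns feature, class, n, W, p_raw, p_adj and
    ``significant_at_0.05`` (flag, no rows are deleted).
    """
    rows = []
    b = baseline.to_frame()
    w = week6.to_frame().loc[b.index]
    for feat in baseline.features:
        try:
            stat, p = wilcoxon_signed_rank(b[feat], w[feat])
        except ValueError as exc:
            logger.warning("feature %s skipped: %s", feat, exc)
            continue
        n = int(np.sum(~np.isnan(w[feat].to_numpy()
                                 - b[feat].to_numpy())))
        rows.append((feat, baseline.block_class, n, stat, p))
    df = pd.DataFrame(rows, columns=["feature", "class", "n", "W", "p_raw"])
    if len(df):
        df["p_adj"] = adjust_bh(df["p_raw"].to_numpy(),
                                df["class"].to_numpy())
        df[f"significant_at_{alpha}"] = df["p_adj"] <= alpha
    return df


def delta_change_table(delta_block, alpha: float = 0.05) -> pd.DataFrame:
    """Like :func:`paired_change_table` but starting from a delta block
    (tests deltas against zero)."""
    zeros = delta_block.to_frame() * 0.0
    rows = []
    for feat in delta_block.features:
        d = delta_block.to_frame()[feat]
        try:
            stat, p = wilcoxon_signed_rank(zeros[feat], d)
        except ValueError as exc:
            logger.warning("feature %s skipped: %s", feat, exc)
            continue
        rows.append((feat, delta_block.block_class,
                     int(np.sum(~np.isnan(d.to_numpy()))), stat, p))
    df = pd.DataFrame(rows, columns=["feature", "class", "n", "W", "p_raw"])
    if len(df):
        df["p_adj"] = adjust_bh(df["p_raw"].to_numpy(),
                                df["class"].to_numpy())
        df[f"significant_at_{alpha}"] = df["p_adj"] <= alpha
    return df
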