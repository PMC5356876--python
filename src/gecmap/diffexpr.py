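"""Per-dataset differential expression and significant-gene selection.

Intensities are floored at a small positive constant and log2-transformed,
then compared between mutant and wild-type samples with an unpaired
two-sample t-test per probe. A probe is significant when its p-value is
below alpha = 1/n (n = probes tested, a Bonferroni-flavoured rule that
bounds the expected number of false positives per dataset at one) and its
fold change exceeds 1.2 in either direction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DIFF_COLUMNS, ExpressionDataset, RankedGeneList
from .errors import InputError, ParameterError

DEFAULT_FC_THRESHOLD = 1.2
DEFAULT_FLOOR = 1.0


def differential_stats(ds: ExpressionDataset, *, equal_var: bool = False,
                       floor: float = DEFAULT_FLOOR) -> pd.DataFrame:
    """Two-sided t-test of MT vs WT per probe on log2 intensities.

    Parameters
    ----------
    ds : expression dataset with both groups populated (>=2 samples each).
    equal_var : use the pooled-variance (Student) t-test instead of the
        default Welch test.
    floor : intensities are clipped from below at this constant before the
        log2 transform, guarding against zeros in linear-scale input.

    Returns
    -------
    DataFrame with columns probe, p_value, log_ratio (mean log2 MT - mean
    log2 WT), fold_change (2^|log_ratio|), sign (+1/-1, the direction in
    the mutant group; +1 when log_ratio == 0). Probes that are constant
    and equal across both groups get p = 1.
    """
    if floor <= 0:
        raise ParameterError("floor must be > 0")
    mt = np.log2(np.maximum(ds.group_matrix("MT"), floor))
    wt = np.log2(np.maximum(ds.group_matrix("WT"), floor))
    if mt.shape[1] < 2 or wt.shape[1] < 2:
        raise InputError("both groups need >=2 samples for a t-test")

    res = stats.ttest_ind(mt, wt, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    log_ratio = mt.mean(axis=1) - wt.mean(axis=1)
    # zero variance in both groups: scipy returns NaN; equal means are a
    # definite non-finding (p = 1), unequal means an infinitely strong one.
    degenerate = ~np.isfinite(p)
    p[degenerate & (log_ratio == 0)] = 1.0
    p[degenerate & (log_ratio != 0)] = 0.0

    sign = np.where(log_ratio < 0, -1, 1)
    return pd.DataFrame({
        "probe": ds.probe_ids,
        "p_value": p,
        "log_ratio": log_ratio,
        "fold_change": np.exp2(np.abs(log_ratio)),
        "sign": sign,
    }, columns=DIFF_COLUMNS)


def select_significant(diff: pd.DataFrame, alpha: float | None = None,
                       fc_threshold: float = DEFAULT_FC_THRESHOLD,
                       name: str = "") -> RankedGeneList:
    """Select and order significant probes from a differential-stats table.

    Keeps probes with p < alpha AND fold_change > fc_threshold, sorted
    primarily by ascending p-value, secondarily by descending |log_ratio|,
    with probe identifier as the deterministic tertiary tie-break. Ranks
    are 1-based (rank 1 = most significant).

    ``alpha`` defaults to 1/n with n the number of probes in ``diff``.
    """
    n = len(diff)
    if alpha is None:
        if n == 0:
            alpha = 0.5  # vacuous: an empty table selects nothing
        else:
            alpha = 1.0 / n
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if fc_threshold < 1.0:
        raise ParameterError(f"fc_threshold must be >= 1, got {fc_threshold}")

    kept = diff[(diff["p_value"] < alpha)
                & (diff["fold_change"] > fc_threshold)].copy()
    kept["_abs_lr"] = kept["log_ratio"].abs()
    kept = kept.sort_values(["p_value", "_abs_lr", "probe"],
                            ascending=[True, False, True], kind="mergesort")
    kept = kept.drop(columns=["_abs_lr", "fold_change"]).reset_index(drop=True)
    kept["rank"] = np.arange(1, len(kept) + 1)
    table = kept[["probe", "sign", "p_value", "log_ratio", "rank"]]
    return RankedGeneList(table=table, n_tested=n, name=name)
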