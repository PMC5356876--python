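"""Direction-of-action validation against cell-line drug-screen data.

Predicted reverser drugs should be more potent in mutant than in
wild-type cell lines. Screen rows carry a sensitivity value per (cell
line, drug) with AUC/IC50 semantics — smaller means more sensitive — so
a drug "agrees" with its predicted direction when the mean sensitivity
value of the mutant lines is strictly below that of the wild-type lines.
Cell lines with extreme copy number (a configurable cutoff, default > 8)
are discarded as genetic outliers before comparison.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .datatypes import DIRECTION_COLUMNS, MT, WT
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_COPY_NUMBER_MAX = 8.0
DEFAULT_ABS_MEAN_THRESHOLD = 0.25


def filter_cell_lines(table: pd.DataFrame, disease_filter: str | None = None,
                      copy_number_max: float = DEFAULT_COPY_NUMBER_MAX,
                      ) -> dict[str, pd.DataFrame]:
    """Disease filtering, outlier removal and MT/WT partitioning.

    Keeps rows whose disease_label equals ``disease_filter`` (None keeps
    all), discards cell lines whose copy number strictly exceeds
    ``copy_number_max`` (logged), and returns ``{"MT": ..., "WT": ...}``.
    """
    if copy_number_max < 0:
        raise ParameterError("copy_number_max must be >= 0")
    kept = table
    if disease_filter is not None:
        kept = kept[kept["disease_label"] == disease_filter]
    if len(kept) == 0:
        raise InputError(f"disease filter {disease_filter!r} matched no rows")

    outliers = sorted(set(kept.loc[kept["copy_number"] > copy_number_max, "cell_line"]))
    if outliers:
        logger.info("discarding %d genetic-outlier cell line(s) with copy "
                    "number > %g: %s", len(outliers), copy_number_max,
                    ", ".join(outliers))
    kept = kept[~kept["cell_line"].isin(outliers)]
    if len(kept) == 0:
        raise InputError("copy-number filter removed every row")
    return {MT: kept[kept["kras_status"] == MT],
            WT: kept[kept["kras_status"] == WT]}


def direction_of_action(partitioned: dict[str, pd.DataFrame],
                        drug: str) -> pd.Series | None:
    """Mean-sensitivity comparison of one drug between MT and WT lines.

    Returns a Series with drug, mean_MT, mean_WT, more_sensitive_in_MT
    (strict mean_MT < mean_WT; ties count as disagreement), n_MT, n_WT —
    or None (with a warning) when the drug is missing from a partition.
    Missing sensitivity values are dropped per group.
    """
    values = {}
    for grp in (MT, WT):
        vals = partitioned[grp].loc[partitioned[grp]["drug"] == drug,
                                    "sensitivity_value"].dropna()
        if len(vals) == 0:
            warnings.warn(f"drug {drug!r} absent from the {grp} partition; "
                          "skipped", stacklevel=2)
            return None
        values[grp] = vals
    mean_mt = float(values[MT].mean())
    mean_wt = float(values[WT].mean())
    return pd.Series(
        [drug, mean_mt, mean_wt, bool(mean_mt < mean_wt),
         len(values[MT]), len(values[WT])],
        index=DIRECTION_COLUMNS)


def agreement_rate(predictions: pd.DataFrame, screen: pd.DataFrame,
                   abs_mean_threshold: float = DEFAULT_ABS_MEAN_THRESHOLD,
                   disease_filter: str | None = None,
                   copy_number_max: float = DEFAULT_COPY_NUMBER_MAX,
                   ) -> tuple[float, pd.DataFrame]:
    """Fraction of strongly predicted reversers more sensitive in MT lines.

    Evaluates the drugs of the combined score table that (i) appear in the
    screen, (ii) have absMeanscore strictly above ``abs_mean_threshold``
    and (iii) have a negative mean score (predicted reversers; positively
    scored drugs are outside the predicted direction and are not
    evaluated). Returns (fraction agreeing, per-drug direction table).
    """
    partitioned = filter_cell_lines(screen, disease_filter=disease_filter,
                                    copy_number_max=copy_number_max)
    screened = set(screen["drug"])
    candidates = predictions[
        predictions["Drug"].isin(screened)
        & (predictions["absMeanscore"] > abs_mean_threshold)
        & (predictions["Meanscore"] < 0)]
    if len(candidates) == 0:
        raise InputError("no predicted reverser above the threshold overlaps "
                         "the screen")

    rows = []
    for drug in candidates.sort_values("Rank")["Drug"]:
        rec = direction_of_action(partitioned, drug)
        if rec is not None:
            rows.append(rec)
    if not rows:
        raise InputError("no overlapping drug present in both MT and WT "
                         "partitions")
    table = pd.DataFrame(rows).reset_index(drop=True)
    fraction = float(np.mean(table["more_sensitive_in_MT"].astype(bool)))
    return fraction, table
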