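"""Nested sub-signature ensemble: run connectivity mapping for every
prefix of the combined signature and recombine the resulting drug lists
into one prioritised drug table.

Each of the L prefix runs yields a list of significant drugs ordered by
|z|; a drug at rank i of a list of M scores sign(z) * (M - i + 1)/M and
non-significant drugs score 0. The L signed scores per drug are summed
(sum score in [-L, L]), the mean is sum/L, and drugs are prioritised by
absolute mean score. Drugs whose sum is exactly zero are dropped. A
consistently top-ranked reverser therefore approaches a mean score of
-1, the strongest possible evidence of reversal across signature lengths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DRUGSCORE_COLUMNS, ReferenceDB, SubSignatureSeries
from .errors import InputError
from .cmap import DEFAULT_N_PERM, significant_drug_list
from .utils import derive_seed


def run_ensemble(series: SubSignatureSeries, db: ReferenceDB,
                 n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                 alpha: float | None = None) -> list[pd.DataFrame]:
    """Significant-drug lists for every prefix 1..L of the series.

    Per-prefix seeds are derived deterministically from the master seed so
    the permutation nulls of different signature lengths are independent
    but the whole run is reproducible.
    """
    if len(series) < 1:
        raise InputError("sub-signature series is empty")
    lists = []
    for k, prefix in enumerate(series, start=1):
        lists.append(significant_drug_list(
            prefix, db, n_perm=n_perm, seed=derive_seed(seed, "prefix", k),
            alpha=alpha))
    return lists


def score_drug_list(drug_list: pd.DataFrame) -> dict[str, float]:
    """Signed normalised rank scores for one significant-drug list.

    The drug at rank i of M gets sign(z) * (M - i + 1)/M; drugs absent
    from the list (non-significant in that run) implicitly score 0.
    """
    M = len(drug_list)
    if M == 0:
        return {}
    ranks = drug_list["rank"].to_numpy()
    z_signs = np.where(drug_list["z_score"].to_numpy() < 0, -1.0, 1.0)
    scores = z_signs * (M - ranks + 1) / M
    return dict(zip(drug_list["drug"], scores))


def combine_drug_lists(lists: list[pd.DataFrame], L: int | None = None,
                       db: ReferenceDB | None = None) -> pd.DataFrame:
    """Sum the L per-list drug scores into the final prioritised table.

    Returns a DataFrame with columns Drug, Replicates, Sumscore, Meanscore,
    absMeanscore, Rank: sum over all L lists (absent drugs contribute 0),
    mean = sum / L, drugs with an exactly zero sum dropped, ordered by
    absolute mean score descending with drug identifier as tie-break.
    ``db`` supplies the replicate counts when available.
    """
    if L is None:
        L = len(lists)
    if L != len(lists):
        raise InputError(f"L = {L} does not match the {len(lists)} supplied lists")
    if L == 0:
        raise InputError("no drug lists to combine")

    totals: dict[str, float] = {}
    for drug_list in lists:
        for drug, score in score_drug_list(drug_list).items():
            totals[drug] = totals.get(drug, 0.0) + score

    replicates = {}
    if db is not None:
        replicates = dict(zip(db.drug_meta["drug"], db.drug_meta["replicates"]))

    rows = [(drug, replicates.get(drug, pd.NA), total, total / L, abs(total) / L)
            for drug, total in totals.items() if total != 0.0]
    table = pd.DataFrame(rows, columns=DRUGSCORE_COLUMNS[:5])
    table = table.sort_values(["absMeanscore", "Drug"], ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table["Rank"] = np.arange(1, len(table) + 1)
    return table[DRUGSCORE_COLUMNS]


def score_trajectories(lists: list[pd.DataFrame],
                       drugs: list[str] | None = None) -> pd.DataFrame:
    """Per-drug normalised score as a function of prefix length.

    Long-format table (prefix_length, drug, score) for plotting how a
    drug's evidence accumulates across the nested signature series.
    """
    records = []
    for k, drug_list in enumerate(lists, start=1):
        scores = score_drug_list(drug_list)
        keys = drugs if drugs is not None else sorted(scores)
        for drug in keys:
            records.append((k, drug, scores.get(drug, 0.0)))
    return pd.DataFrame(records, columns=["prefix_length", "drug", "score"])
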