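"""Combining per-dataset gene lists into one signed query signature.

Each dataset's significant genes are scored with the normalised rank
score sign * (M - i + 1)/M (M = list length, i = 1-based rank), so the
top gene of any list scores +/-1 and the last scores +/-1/M regardless
of list length. Per-probe scores are summed across datasets; genes that
regulate in opposite directions partially cancel, and genes with a zero
total are dropped. The surviving genes, ordered by absolute total score,
form the combined signature, whose nested prefixes (top-1, top-2, ...)
are the sub-signature series fed to connectivity mapping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (SIGNATURE_COLUMNS, CombinedSignature, RankedGeneList,
                        SubSignatureSeries)
from .errors import InputError


def gene_rank_score(ranked: RankedGeneList) -> dict[str, float]:
    """Signed normalised rank score per probe: sign * (M - i + 1) / M.

    Probes absent from the list implicitly score 0 (they are simply not
    in the returned mapping).
    """
    if ranked.M == 0:
        return {}
    M = ranked.M
    t = ranked.table
    scores = t["sign"].to_numpy() * (M - t["rank"].to_numpy() + 1) / M
    return dict(zip(t["probe"], scores))


def combine_signatures(lists: list[RankedGeneList]) -> CombinedSignature:
    """Sum signed rank scores across datasets into the combined signature.

    Ordering: absolute total score descending; ties broken by the smallest
    per-dataset p-value (ascending), then probe identifier.
    """
    if not lists:
        raise InputError("at least one ranked gene list is required")

    universes = [set(l.table["probe"]) for l in lists]
    if len(universes) > 1 and all(universes[0].isdisjoint(u) for u in universes[1:]):
        warnings.warn("probe namespaces of the ranked lists are disjoint; "
                      "taking their union", stacklevel=2)

    totals: dict[str, float] = {}
    best_p: dict[str, float] = {}
    for ranked in lists:
        for probe, score in gene_rank_score(ranked).items():
            totals[probe] = totals.get(probe, 0.0) + score
        for probe, p in zip(ranked.table["probe"], ranked.table["p_value"]):
            best_p[probe] = min(best_p.get(probe, np.inf), p)

    rows = [(probe, total, 1 if total > 0 else -1, best_p[probe])
            for probe, total in totals.items() if total != 0.0]
    table = pd.DataFrame(rows, columns=["probe", "total_score", "sign", "_min_p"])
    table["_abs"] = table["total_score"].abs()
    table = table.sort_values(["_abs", "_min_p", "probe"],
                              ascending=[False, True, True], kind="mergesort")
    table = table.drop(columns=["_abs", "_min_p"]).reset_index(drop=True)
    return CombinedSignature(table=table[SIGNATURE_COLUMNS])


def make_subsignatures(sig: CombinedSignature,
                       max_length: int | None = None) -> SubSignatureSeries:
    """The nested prefix series: prefix k holds the top-k signature genes.

    ``max_length`` optionally truncates the series (prefixes 1..max_length)
    for scaled-down runs; by default all L prefixes are produced.
    """
    if sig.L < 1:
        raise InputError("cannot derive sub-signatures from an empty signature")
    return SubSignatureSeries(sig, max_length=max_length)
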