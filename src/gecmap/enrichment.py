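"""Hypergeometric over-representation tests.

Two applications share one primitive: enrichment of a drug class (theme)
among the top-ranked candidate drugs, with the full drug collection as
the background population; and enrichment of pathway membership among
the signature genes, with all probes tested for differential expression
(restricted to those mappable to at least one pathway) as the background.
Both report the exact upper-tail probability P(X >= k_obs) of the
hypergeometric distribution, uncorrected for multiplicity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ENRICHMENT_COLUMNS, CombinedSignature
from .errors import ParameterError

DEFAULT_TOP_K = 30


def hypergeom_upper(N_pop: int, K: int, n_draw: int, k_obs: int) -> float:
    """Exact upper tail P(X >= k_obs), X ~ Hypergeometric(N_pop, K, n_draw).

    Population of N_pop with K successes, n_draw draws without
    replacement; returns the probability of observing k_obs or more
    successes. Bounds are enforced strictly (k_obs beyond min(K, n_draw)
    is a caller error, not a zero).
    """
    if not (0 <= K <= N_pop):
        raise ParameterError(f"K = {K} outside 0..{N_pop}")
    if not (0 <= n_draw <= N_pop):
        raise ParameterError(f"n_draw = {n_draw} outside 0..{N_pop}")
    if not (0 <= k_obs <= min(K, n_draw)):
        raise ParameterError(
            f"k_obs = {k_obs} outside 0..min(K, n_draw) = {min(K, n_draw)}")
    return float(stats.hypergeom.sf(k_obs - 1, N_pop, K, n_draw))


def drug_theme_enrichment(table: pd.DataFrame, themes: dict[str, str],
                          top_k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Theme over-representation among the top_k drugs of a score table.

    ``table`` is the combined drug-score table (must carry Drug and Rank
    columns, ordered by absolute mean score); ``themes`` maps each drug of
    the full collection to its class label. K per theme counts members in
    the whole collection, k_obs counts members among the top_k.
    """
    if top_k > len(table):
        raise ParameterError(
            f"top_k = {top_k} exceeds the {len(table)} drugs in the table")

    N_pop = len(themes)
    top = list(table.sort_values("Rank").head(top_k)["Drug"])
    unlabelled = sorted(d for d in top if d not in themes)
    if unlabelled:
        warnings.warn(f"{len(unlabelled)} top-ranked drug(s) missing from the "
                      f"theme map are ignored: {unlabelled[:5]}", stacklevel=2)
    records = []
    for theme in sorted(set(themes.values())):
        members = {d for d, t in themes.items() if t == theme}
        K = len(members)
        k_obs = sum(1 for d in top if d in members)
        p = hypergeom_upper(N_pop, K, top_k, k_obs)
        records.append((theme, N_pop, K, top_k, k_obs, p))
    out = pd.DataFrame(records, columns=ENRICHMENT_COLUMNS)
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def pathway_overrepresentation(sig: CombinedSignature,
                               pathways: dict[str, list[str]],
                               background: set[str],
                               p_cut: float = 0.05) -> pd.DataFrame:
    """Pathway over-representation among signature probes.

    ``background`` is the set of probes eligible for the test (all probes
    entering differential analysis that map to at least one pathway, by
    default); pathway membership and the signature are both intersected
    with it. Output columns: label, population_size, successes_in_population
    (pathway members in background), draws (signature probes in
    background), observed (overlap), p_value, significant; sorted by
    p ascending.
    """
    sig_probes = {p for p in sig.probes if p in background}
    N_pop = len(background)
    records = []
    for name, members in pathways.items():
        member_set = set(members) & background
        if not member_set:
            warnings.warn(f"pathway {name!r} has no members in the background; "
                          "skipped", stacklevel=2)
            continue
        k_obs = len(sig_probes & member_set)
        p = hypergeom_upper(N_pop, len(member_set), len(sig_probes), k_obs)
        records.append((name, N_pop, len(member_set), len(sig_probes), k_obs, p))
    out = pd.DataFrame(records, columns=ENRICHMENT_COLUMNS)
    out = out.sort_values(["p_value", "label"], kind="mergesort").reset_index(drop=True)
    out["significant"] = out["p_value"] < p_cut
    return out
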