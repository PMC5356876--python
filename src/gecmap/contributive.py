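"""Contributive-gene analysis: which signature probes drive a drug's
inverse connection, and how the contributive sets of several drugs
overlap.

For a drug, each signature probe's mean signed rank across the drug's
treatment-instance profiles is multiplied by the probe's regulation
status in the signature (+1 up, -1 down in the mutant condition). A
negative product means the drug moves that probe against its disease
regulation — the probe contributes to the (negative) reversal
connection. Overlapping the contributive sets of related drugs exposes
a common candidate mechanism of action.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .datatypes import CONTRIBUTION_COLUMNS, CombinedSignature, ReferenceDB
from .errors import InputError


def probe_contributions(db: ReferenceDB, drug_id: str,
                        sig: CombinedSignature) -> pd.DataFrame:
    """Per-signature-probe contribution records for one drug.

    Columns: probe, mean_signed_rank (over the drug's instances),
    regulation (signature sign), contribution (= mean_signed_rank *
    regulation), contribution_normalized (contribution / N, for
    cross-database comparability), contributive (contribution < 0,
    strictly). Signature order is preserved.
    """
    if sig.L == 0:
        raise InputError("empty signature")
    cols = db.probe_columns(sig.probes)
    rows = db.instances_of(drug_id)
    mean_sr = db.signed_ranks[np.ix_(rows, cols)].mean(axis=0)
    regulation = sig.signs
    contribution = mean_sr * regulation
    return pd.DataFrame({
        "probe": sig.probes,
        "mean_signed_rank": mean_sr,
        "regulation": regulation,
        "contribution": contribution,
        "contribution_normalized": contribution / db.N,
        "contributive": contribution < 0,
    }, columns=CONTRIBUTION_COLUMNS)


def contributive_set(db: ReferenceDB, drug_id: str,
                     sig: CombinedSignature) -> set[str]:
    """The set of contributive probes (contribution strictly negative)."""
    table = probe_contributions(db, drug_id, sig)
    return set(table.loc[table["contributive"], "probe"])


def overlap_contributive(sets: dict[str, set[str]]) -> dict:
    """Venn-region analysis of 2-4 named probe sets.

    Returns a dict with:

    - ``regions``: DataFrame (membership pattern as a string of set names,
      count, probes) covering every non-empty combination of sets; counts
      sum to the union size.
    - ``core``: sorted probes present in every set.
    - ``near_core``: sorted probes present in at least (number of sets - 1)
      sets (the "3 of 4" tier; equals the union for two sets).
    """
    names = list(sets)
    if len(names) != len(set(names)):
        raise InputError("duplicate set names")
    if not 2 <= len(names) <= 4:
        raise InputError(f"overlap analysis supports 2-4 sets, got {len(names)}")

    union = set().union(*sets.values())
    records = []
    for k in range(1, len(names) + 1):
        for inside in combinations(names, k):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                region -= sets[n]
            records.append(("&".join(inside), len(region), sorted(region)))
    regions = pd.DataFrame(records, columns=["region", "count", "probes"])

    core = set.intersection(*sets.values())
    k_min = len(names) - 1
    near_core = {p for p in union
                 if sum(p in s for s in sets.values()) >= k_min}
    assert int(regions["count"].sum()) == len(union)
    return {"regions": regions, "core": sorted(core), "near_core": sorted(near_core)}
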