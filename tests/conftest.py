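"""Shared fixtures: one desk-scale synthetic study generated once per
session, plus a handcrafted miniature reference database for exact tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gecmap import (CombinedSignature, ReferenceDB, SimulationConfig,
                    gen_expression_datasets, gen_reference_db)


@pytest.fixture(scope="session")
def desk_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def study(desk_config):
    """(datasets, truth, db) of the default desk-scale synthetic study."""
    datasets, truth = gen_expression_datasets(desk_config)
    db = gen_reference_db(desk_config, truth)
    return datasets, truth, db


@pytest.fixture(scope="session")
def study_signature(study):
    from gecmap import combine_signatures, differential_stats, select_significant
    datasets, _, _ = study
    ranked = [select_significant(differential_stats(ds), name=ds.name)
              for ds in datasets]
    return combine_signatures(ranked)


def make_db(signed_ranks: np.ndarray, drugs: list[str],
            probe_ids: list[str] | None = None,
            themes: list[str] | None = None) -> ReferenceDB:
    """Handcrafted reference database from an explicit signed-rank matrix."""
    signed_ranks = np.asarray(signed_ranks, dtype=np.int64)
    n_inst, N = signed_ranks.shape
    if probe_ids is None:
        probe_ids = [f"g{i + 1}" for i in range(N)]
    counts = pd.Series(drugs).value_counts()
    meta = pd.DataFrame({
        "drug": sorted(counts.index),
        "theme": themes if themes is not None else ["none"] * len(counts),
        "replicates": [counts[d] for d in sorted(counts.index)],
    })
    return ReferenceDB(
        probe_ids=np.array(probe_ids, dtype=object),
        signed_ranks=signed_ranks,
        instance_drugs=np.array(drugs, dtype=object),
        instance_ids=np.array([f"inst{i}" for i in range(n_inst)], dtype=object),
        drug_meta=meta)


def make_signature(probes: list[str], signs: list[int]) -> CombinedSignature:
    """Combined signature with descending placeholder scores."""
    n = len(probes)
    scores = np.asarray(signs, dtype=float) * np.linspace(n, 1, n)
    return CombinedSignature(table=pd.DataFrame(
        {"probe": probes, "total_score": scores, "sign": signs}))
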