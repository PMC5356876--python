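"""Generator contracts: determinism, planted structure, null calibration."""

import numpy as np
import pytest

from gecmap import (ConfigurationError, SimulationConfig, connection_score,
                    differential_stats, gen_expression_datasets,
                    gen_reference_db, gen_sensitivity_screen, select_significant)
from gecmap.datatypes import MT, WT


def small(**kw):
    params = dict(n_probes=400, n_true_de=40, n_drugs=20, n_reversers=3,
                  samples_per_group=((20, 20), (15, 15)), n_datasets=2,
                  replicates_range=(2, 5), seed=5)
    params.update(kw)
    return SimulationConfig(**params)


@pytest.mark.parametrize("field,value", [
    ("n_probes", 0), ("n_true_de", 500), ("n_reversers", 30),
    ("noise_sd", -1.0), ("frac_shared", 1.5), ("replicates_range", (0, 4)),
    ("samples_per_group", ((1, 20), (15, 15))),
])
def test_invalid_config_rejected(field, value):
    with pytest.raises(ConfigurationError):
        small(**{field: value})


def test_expression_determinism_and_shape():
    a, truth_a = gen_expression_datasets(small())
    b, truth_b = gen_expression_datasets(small())
    assert truth_a.planted_signs == truth_b.planted_signs
    for da, db_ in zip(a, b):
        assert np.array_equal(da.intensities, db_.intensities)
        assert set(da.groups) == {MT, WT}
        assert np.all(da.intensities > 0)  # linear scale
    c, _ = gen_expression_datasets(small(seed=6))
    assert not np.array_equal(a[0].intensities, c[0].intensities)


def test_null_effect_selection_matches_chance_rate():
    """With no planted effect the p < 1/n count stays near its nominal
    expectation of one per dataset."""
    datasets, _ = gen_expression_datasets(small(effect_log2=0.0, seed=21))
    for ds in datasets:
        diff = differential_stats(ds)
        hits = int((diff["p_value"] < 1.0 / len(diff)).sum())
        assert hits <= 8  # Poisson(1), P(X > 8) ~ 1e-7
        sel = select_significant(diff)
        assert sel.M <= hits


def test_planted_probes_recovered_per_dataset():
    """>=90% of planted probes pass p < 1/n and FC > 1.2 in each dataset
    (Monte-Carlo power of the planted normal model is ~0.9999)."""
    config = SimulationConfig(n_probes=2000, n_true_de=100, effect_log2=1.0,
                              noise_sd=0.5, frac_shared=1.0, n_datasets=1,
                              samples_per_group=((30, 30),), seed=42)
    datasets, truth = gen_expression_datasets(config)
    diff = differential_stats(datasets[0])
    sel = select_significant(diff)
    selected = dict(zip(sel.table["probe"], sel.table["sign"]))
    recovered = sum(1 for p, s in truth.planted_signs.items()
                    if selected.get(p) == s)
    assert recovered >= 90


def test_reference_db_signed_rank_invariant(study):
    _, _, db = study
    db.validate_ranks()
    assert set(np.unique(np.sign(db.signed_ranks))) <= {-1, 1}
    assert db.D == 200
    counts = dict(zip(db.drug_meta["drug"], db.drug_meta["replicates"]))
    for drug in db.drugs:
        assert len(db.instances_of(drug)) == counts[drug] >= 1


def test_reference_db_determinism():
    cfg = small()
    _, truth = gen_expression_datasets(cfg)
    db1 = gen_reference_db(cfg, truth)
    db2 = gen_reference_db(cfg, truth)
    assert np.array_equal(db1.signed_ranks, db2.signed_ranks)


def test_maximal_reverser_scores_minus_one():
    """At reverser strength 1 the planted signature scores exactly -1
    against every reverser instance."""
    cfg = small(reverser_strength=1.0)
    _, truth = gen_expression_datasets(cfg)
    db = gen_reference_db(cfg, truth)
    probes = sorted(truth.planted_signs)
    signs = [truth.planted_signs[p] for p in probes]
    rev = truth.reverser_drugs[0]
    for row in db.instances_of(rev):
        profile = dict(zip(db.probe_ids, db.signed_ranks[row]))
        assert connection_score((probes, signs), profile) == pytest.approx(-1.0)


def test_random_drug_scores_centred_on_zero(study):
    """Mean connection score of non-reverser instances vs the planted
    signature stays within 3 SE of 0 (permutation-null variance)."""
    from gecmap.cmap import max_raw
    datasets, truth, db = study
    probes = sorted(truth.planted_signs)
    signs = np.array([truth.planted_signs[p] for p in probes])
    cols = db.probe_columns(np.array(probes, dtype=object))
    non_rev = ~np.isin(db.instance_drugs, truth.reverser_drugs)
    scores = (db.signed_ranks[np.ix_(np.flatnonzero(non_rev), cols)]
              @ signs) / max_raw(db.N, len(probes))
    # null variance of one score: sum E[r^2]/maxraw^2 over m draws
    m, N = len(probes), db.N
    var1 = m * np.mean(np.arange(1, N + 1) ** 2.0) / max_raw(N, m) ** 2
    se = np.sqrt(var1 / len(scores))
    assert abs(scores.mean()) < 3 * se


def test_screen_structure_and_planted_outlier():
    cfg = small()
    _, truth = gen_expression_datasets(cfg)
    gen_reference_db(cfg, truth)   # records the reverser identities
    screen = gen_sensitivity_screen(cfg, truth)
    assert set(truth.sensitive_drugs) == set(truth.reverser_drugs)
    outliers = screen.loc[screen["copy_number"] > 8, "cell_line"].unique()
    assert len(outliers) == 1
    status = screen.drop_duplicates("cell_line").set_index("cell_line")["kras_status"]
    assert status[outliers[0]] == WT
    assert (status == MT).sum() == cfg.mt_cell_lines
    # determinism
    screen2 = gen_sensitivity_screen(cfg, truth)
    assert screen.equals(screen2)


def test_null_screen_direction_is_coin_flip():
    """With no planted shift, per-drug MT-vs-WT direction is ~Bernoulli(0.5)."""
    cfg = small(n_drugs=200, screen_shift=0.0, seed=31)
    _, truth = gen_expression_datasets(cfg)
    screen = gen_sensitivity_screen(cfg, truth)
    means = screen.groupby(["drug", "kras_status"])["sensitivity_value"].mean()
    frac = np.mean([means[d, MT] < means[d, WT] for d in cfg.drug_names()])
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 200)


def test_planted_shift_gives_near_certain_agreement():
    """shift = -0.1 at noise 0.1 with 24/25 lines: P(MT mean < WT mean)
    ~ Phi(3.5) ~ 0.9998 per sensitive drug (closed-form normal oracle)."""
    cfg = SimulationConfig(seed=13)
    _, truth = gen_expression_datasets(cfg)
    screen = gen_sensitivity_screen(cfg, truth)
    means = screen.groupby(["drug", "kras_status"])["sensitivity_value"].mean()
    agree = [means[d, MT] < means[d, WT] for d in truth.sensitive_drugs]
    assert all(agree)
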