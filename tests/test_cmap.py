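"""Connection scoring, permutation nulls and per-drug significance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gecmap import (InputError, ParameterError, all_drug_connections,
                    connection_score, drug_connection, instance_null,
                    significant_drug_list)
from gecmap.cmap import max_raw, sample_null_magnitudes
from conftest import make_db


@pytest.fixture
def profile5():
    """N = 5 profile: signed ranks g1..g5 = +5, -4, +3, -2, +1."""
    return {"g1": 5, "g2": -4, "g3": 3, "g4": -2, "g5": 1}


def test_max_raw_is_sum_of_top_magnitudes():
    assert max_raw(5, 2) == 9
    assert max_raw(5, 5) == 15
    assert max_raw(22268, 248) == sum(range(22268, 22268 - 248, -1))
    with pytest.raises(InputError):
        max_raw(3, 4)


def test_maximal_alignment_and_reversal(profile5):
    sig = (["g1", "g2"], [1, -1])       # top-2 magnitudes, matching signs
    assert connection_score(sig, profile5) == pytest.approx(1.0)
    flipped = (["g1", "g2"], [-1, 1])
    assert connection_score(flipped, profile5) == pytest.approx(-1.0)


def test_hand_computed_example(profile5):
    # signature {(g1,+),(g2,-)} with ranks g1=+5, g2=+3: (5-3)/(5+4) = 2/9
    profile = {"g1": 5, "g2": 3, "g3": -4, "g4": -2, "g5": 1}
    score = connection_score((["g1", "g2"], [1, -1]), profile)
    assert score == pytest.approx(2 / 9)


def test_missing_probe_is_an_error(profile5):
    with pytest.raises(InputError, match="gX"):
        connection_score((["g1", "gX"], [1, 1]), profile5)


def test_brute_force_oracle_all_two_gene_signatures(profile5):
    """Every 2-gene signature's score equals an independently computed
    signed-rank sum over the enumeration of all such signatures."""
    genes = sorted(profile5)
    for pair in itertools.combinations(genes, 2):
        for signs in itertools.product([-1, 1], repeat=2):
            expected = sum(s * profile5[g] for g, s in zip(pair, signs)) / 9
            assert connection_score((list(pair), list(signs)),
                                    profile5) == pytest.approx(expected)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.integers(2, 12), st.integers(1, 6))
def test_antisymmetry_and_bounds(seed, N, m):
    """Flipping all signature signs negates every connection score, and
    all scores lie in [-1, 1]."""
    m = min(m, N)
    rng = np.random.default_rng(seed)
    ranks = (rng.permutation(N) + 1) * rng.choice([-1, 1], N)
    profile = {f"g{i}": int(r) for i, r in enumerate(ranks)}
    probes = list(rng.choice(sorted(profile), size=m, replace=False))
    signs = list(rng.choice([-1, 1], size=m))
    s = connection_score((probes, signs), profile)
    assert -1.0 <= s <= 1.0
    assert connection_score((probes, [-x for x in signs]),
                            profile) == pytest.approx(-s)


def test_score_invariant_to_probe_relabelling(profile5):
    relabel = {f"g{i}": f"probe_{i}" for i in range(1, 6)}
    renamed = {relabel[g]: r for g, r in profile5.items()}
    sig = (["g2", "g4"], [1, -1])
    sig_renamed = ([relabel[p] for p in sig[0]], sig[1])
    assert connection_score(sig, profile5) == connection_score(sig_renamed, renamed)


def test_null_sampling_without_replacement():
    rng = np.random.default_rng(0)
    mags = sample_null_magnitudes(4, 10, 500, rng)
    assert mags.shape == (500, 4)
    assert all(len(set(row)) == 4 for row in mags)
    assert mags.min() >= 1 and mags.max() <= 10


def test_instance_null_mean_variance_and_determinism():
    N = 6
    null = instance_null(m=N, N=N, n_perm=40_000, seed=3)
    # m = N: score = sum s_r * r / maxraw; var = sum r^2 / maxraw^2 = 0.20635
    var_expected = sum(r * r for r in range(1, N + 1)) / max_raw(N, N) ** 2
    assert null.mean() == pytest.approx(0.0, abs=3 * np.sqrt(var_expected / 40_000))
    assert null.var() == pytest.approx(var_expected, rel=0.05)
    assert np.array_equal(null, instance_null(m=N, N=N, n_perm=40_000, seed=3))
    with pytest.raises(ParameterError):
        instance_null(2, 6, n_perm=500)
    with pytest.raises(InputError):
        instance_null(7, 6, n_perm=1000)


def test_empirical_p_matches_enumeration_tail():
    """For N = 5, m = 2 the permutation p-value of a single-instance drug
    matches the exact tail over all C(5,2) * 4 equally likely signatures."""
    ranks = np.array([[5, -4, 3, -2, 1]])
    db = make_db(ranks, ["drugA"])
    sig = (["g1", "g3"], [1, 1])        # raw = 5 + 3 = 8, score 8/9
    obs = connection_score(sig, {f"g{i+1}": int(r) for i, r in enumerate(ranks[0])})
    scores = []
    for pair in itertools.combinations(range(5), 2):
        for signs in itertools.product([-1, 1], repeat=2):
            scores.append(sum(s * ranks[0][i] for i, s in zip(pair, signs)) / 9)
    exact_tail = np.mean(np.abs(scores) >= abs(obs))
    res = drug_connection(sig, db, "drugA", n_perm=20_000, seed=5)
    assert res.set_score == pytest.approx(obs)
    se = np.sqrt(exact_tail * (1 - exact_tail) / 20_000)
    assert res.p_value == pytest.approx(exact_tail, abs=4 * se + 1e-4)


def test_maximal_reverser_drug_connection():
    """Every instance holds the signature probes at top magnitude with
    opposite sign: set score -1, minimal attainable p, strongly negative z."""
    N = 30
    rng = np.random.default_rng(1)
    probes = [f"g{i + 1}" for i in range(N)]
    top_idx = np.array([4, 11, 23])
    rows = []
    for _ in range(4):
        ranks = np.empty(N, dtype=int)
        rest = np.setdiff1d(np.arange(N), top_idx)
        ranks[rest] = rng.permutation(N - 3) + 1
        ranks[top_idx] = [N - 2, N - 1, N]
        signs = rng.choice([-1, 1], N)
        signs[top_idx] = -1
        rows.append(ranks * signs)
    db = make_db(np.array(rows), ["rev"] * 4, probe_ids=probes)
    sig = ([probes[i] for i in top_idx], [1, 1, 1])
    res = drug_connection(sig, db, "rev", n_perm=2_000, seed=2, alpha=0.01)
    assert res.set_score == pytest.approx(-1.0)
    assert res.p_value == pytest.approx(1 / 2001)
    assert res.z_score < -5
    assert res.significant


def test_symmetric_instances_are_not_significant():
    """A drug whose instance scores cancel symmetrically has small |z|."""
    N = 20
    perm = np.arange(1, N + 1)
    rows = [perm.copy(), -perm.copy()] * 5     # mirror-image instance pairs
    db = make_db(np.array(rows), ["sym"] * 10)
    sig = (["g20", "g19"], [1, 1])
    res = drug_connection(sig, db, "sym", n_perm=2_000, seed=7, alpha=0.01)
    assert res.set_score == pytest.approx(0.0, abs=1e-12)
    assert abs(res.z_score) < 1
    assert not res.significant


def test_significant_list_single_maximal_reverser(study, study_signature):
    """On the planted study the significant list for a short prefix holds
    the reversers and little else."""
    _, truth, db = study
    sig = study_signature
    prefix = (sig.probes[:10], sig.signs[:10])
    result = significant_drug_list(prefix, db, n_perm=2_000, seed=3)
    hits = set(result["drug"])
    assert set(truth.reverser_drugs) <= hits
    assert len(hits - set(truth.reverser_drugs)) <= 2
    # sorted by |z| descending
    z = result["z_score"].abs().to_numpy()
    assert np.all(z[:-1] >= z[1:])


def test_null_calibration_at_nominal_levels():
    """Random-signature significance rates stay within binomial 99% bounds
    of the nominal level (independent single-instance drugs)."""
    N, D = 400, 400
    rng = np.random.default_rng(8)
    ranks = np.array([(rng.permutation(N) + 1) * rng.choice([-1, 1], N)
                      for _ in range(D)])
    db = make_db(ranks, [f"d{i:03d}" for i in range(D)])
    probes = list(rng.choice([f"g{i + 1}" for i in range(N)], 15, replace=False))
    signs = list(rng.choice([-1, 1], 15))
    for alpha in (0.01, 0.05):
        res = all_drug_connections((probes, signs), db, n_perm=2_000, seed=9,
                                   alpha=alpha)
        k = int(res["significant"].sum())
        bound = 2.576 * np.sqrt(D * alpha * (1 - alpha))
        assert abs(k - D * alpha) <= bound + 1


def test_alpha_unattainable_with_small_n_perm(study):
    _, _, db = study
    sig = (["probe_0001"], [1])
    with pytest.raises(ParameterError):
        drug_connection(sig, db, db.drugs[0], n_perm=1_000, alpha=1e-5)
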