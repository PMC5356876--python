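"""Connectivity scoring of a signed query signature against reference
treatment-instance profiles, with permutation significance.

The connection score between a signature of m signed genes and a profile
of signed ranks over N probes is the signed-rank dot product

    raw = sum over signature genes g of sign_sig(g) * signed_rank(g)

normalised by the maximal attainable value maxraw = N + (N-1) + ... +
(N-m+1), so scores lie in [-1, 1]. +1 means the profile's m most
differential probes are exactly the signature genes with matching signs;
-1 the same with all signs opposed, i.e. the drug maximally reverses the
queried condition.

Significance is assessed against an empirical permutation null: random
signatures (m distinct probes uniform without replacement, independent
equiprobable signs) scored the same way. Per-drug set scores (mean over
the drug's treatment instances) are compared against a null of set
scores formed by averaging matching numbers of null instance scores; the
two-sided empirical p-value uses the add-one correction (b+1)/(n_perm+1)
and a drug is called significant at p <= 1/D (D = number of drugs in the
database), bounding the expected number of false connections per
database scan at one.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .datatypes import (CONNECTION_COLUMNS, CombinedSignature, ConnectionResult,
                        ReferenceDB)
from .errors import InputError, ParameterError
from .utils import derive_seed

DEFAULT_N_PERM = 10_000
MIN_N_PERM = 1_000


def max_raw(N: int, m: int) -> int:
    """Maximal attainable raw score: sum of the m largest magnitudes N..N-m+1."""
    if m > N:
        raise InputError(f"signature length {m} exceeds probe universe size {N}")
    if m < 1:
        raise InputError("signature must contain at least one gene")
    return m * N - (m * (m - 1)) // 2


def _as_signature(sig) -> tuple[np.ndarray, np.ndarray]:
    """Accept a CombinedSignature or a (probes, signs) pair."""
    if isinstance(sig, CombinedSignature):
        return sig.probes, sig.signs
    probes, signs = sig
    probes = np.asarray(probes, dtype=object)
    signs = np.asarray(signs, dtype=int)
    if len(probes) != len(signs):
        raise InputError("signature probes and signs differ in length")
    if len(probes) == 0:
        raise InputError("empty query signature")
    if len(set(probes)) != len(probes):
        raise InputError("duplicate probes in query signature")
    if not np.all(np.isin(signs, (-1, 1))):
        raise InputError("signature signs must be +1 or -1")
    return probes, signs


def connection_score(sig, profile: Mapping[str, int] | pd.Series) -> float:
    """Normalised connection score of one signature against one profile.

    ``profile`` maps every probe of the universe to its signed rank
    (magnitudes a permutation of 1..N). Signature probes missing from the
    profile are an error: the platforms involved share one probe universe,
    so a mismatch indicates corrupt input rather than droppable data.
    """
    probes, signs = _as_signature(sig)
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    missing = [p for p in probes if p not in profile]
    if missing:
        raise InputError("signature probes absent from profile: "
                         + ", ".join(map(str, missing[:10])))
    N = len(profile)
    raw = sum(int(s) * int(profile[p]) for p, s in zip(probes, signs))
    return raw / max_raw(N, len(probes))


def sample_null_magnitudes(m: int, N: int, n_draws: int,
                           rng: np.random.Generator) -> np.ndarray:
    """n_draws independent uniform m-subsets of the magnitudes 1..N.

    Vectorised as an argpartition of a uniform matrix: the indices of the
    m smallest entries per row are a uniform without-replacement sample.
    """
    if m > N:
        raise InputError(f"signature length {m} exceeds probe universe size {N}")
    u = rng.random((n_draws, N))
    if m < N:
        idx = np.argpartition(u, m - 1, axis=1)[:, :m]
    else:
        idx = np.tile(np.arange(N), (n_draws, 1))
    return idx + 1


def instance_null(m: int, N: int, n_perm: int = DEFAULT_N_PERM,
                  seed: int = 0) -> np.ndarray:
    """Empirical null sample of normalised scores of random signatures.

    Random signatures take m distinct probes uniformly without replacement
    and independent equiprobable +/-1 signs; by symmetry the null does not
    depend on the fixed profile being scored against, only on (m, N).
    """
    if n_perm < MIN_N_PERM:
        raise ParameterError(f"n_perm must be >= {MIN_N_PERM}, got {n_perm}")
    rng = np.random.default_rng(seed)
    mags = sample_null_magnitudes(m, N, n_perm, rng)
    signs = rng.choice((-1, 1), size=(n_perm, m))
    return (mags * signs).sum(axis=1) / max_raw(N, m)


def _set_null(pool: np.ndarray, r: int, n_perm: int,
              rng: np.random.Generator) -> np.ndarray:
    """Null sample of r-instance set scores from an instance-null pool.

    For r = 1 the pool itself is the null; for r > 1, r draws are
    bootstrap-resampled from the pool per null set score.
    """
    if r == 1:
        return pool
    idx = rng.integers(0, len(pool), size=(n_perm, r))
    return pool[idx].mean(axis=1)


def _instance_scores(db: ReferenceDB, rows: np.ndarray, cols: np.ndarray,
                     signs: np.ndarray) -> np.ndarray:
    sub = db.signed_ranks[np.ix_(rows, cols)]
    return (sub * signs).sum(axis=1) / max_raw(db.N, len(cols))


def _empirical_p(null: np.ndarray, observed: float) -> float:
    b = int(np.sum(np.abs(null) >= abs(observed)))
    return (b + 1) / (len(null) + 1)


def _check_alpha(alpha: float, n_perm: int) -> None:
    if alpha < 1.0 / (n_perm + 1):
        raise ParameterError(
            f"n_perm = {n_perm} cannot resolve significance level {alpha:.3g}; "
            f"minimum attainable p is 1/{n_perm + 1}")


def drug_connection(sig, db: ReferenceDB, drug_id: str,
                    n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                    alpha: float | None = None) -> ConnectionResult:
    """Connectivity of one drug (all its treatment instances) to a signature.

    set_score is the mean instance score; p and z come from the matching
    set-score null; ``significant`` applies p <= alpha (default 1/D).
    """
    probes, signs = _as_signature(sig)
    alpha = 1.0 / db.D if alpha is None else alpha
    _check_alpha(alpha, n_perm)
    cols = db.probe_columns(probes)
    rows = db.instances_of(drug_id)
    inst = _instance_scores(db, rows, cols, signs)
    pool = instance_null(len(probes), db.N, n_perm, derive_seed(seed, "null", len(probes)))
    rng = np.random.default_rng(derive_seed(seed, "boot", len(probes)))
    null = _set_null(pool, len(rows), n_perm, rng)
    set_score = float(inst.mean())
    p = _empirical_p(null, set_score)
    z = (set_score - null.mean()) / null.std(ddof=1)
    return ConnectionResult(drug_id=drug_id, set_score=set_score,
                            z_score=float(z), p_value=float(p),
                            significant=bool(p <= alpha), instance_scores=inst)


def all_drug_connections(sig, db: ReferenceDB, n_perm: int = DEFAULT_N_PERM,
                         seed: int = 0, alpha: float | None = None) -> pd.DataFrame:
    """Connectivity results for every drug in the database (one shared null).

    Returns a DataFrame with columns drug, set_score, z_score, p_value,
    significant, n_instances, in database drug order. The instance-score
    null pool is drawn once per call and shared across drugs; set-score
    nulls are cached per distinct replicate count.
    """
    probes, signs = _as_signature(sig)
    m = len(probes)
    alpha = 1.0 / db.D if alpha is None else alpha
    _check_alpha(alpha, n_perm)
    cols = db.probe_columns(probes)

    raw = db.signed_ranks[:, cols].astype(np.int64) @ signs.astype(np.int64)
    scores = raw / max_raw(db.N, m)

    pool = instance_null(m, db.N, n_perm, derive_seed(seed, "null", m))
    rng = np.random.default_rng(derive_seed(seed, "boot", m))

    null_cache: dict[int, tuple[np.ndarray, float, float]] = {}
    records = []
    drug_rows = pd.Series(np.arange(len(db.instance_drugs))).groupby(
        pd.Series(db.instance_drugs)).groups
    for drug in db.drugs:
        rows = np.asarray(drug_rows[drug], dtype=int)
        r = len(rows)
        if r not in null_cache:
            null = _set_null(pool, r, n_perm, rng)
            null_cache[r] = (np.sort(np.abs(null)), float(null.mean()),
                             float(null.std(ddof=1)))
        abs_sorted, mu, sd = null_cache[r]
        set_score = float(scores[rows].mean())
        b = len(abs_sorted) - int(np.searchsorted(abs_sorted, abs(set_score), side="left"))
        p = (b + 1) / (len(abs_sorted) + 1)
        z = (set_score - mu) / sd
        records.append((drug, set_score, float(z), float(p), bool(p <= alpha), r))
    return pd.DataFrame(records, columns=CONNECTION_COLUMNS)


def significant_drug_list(sig, db: ReferenceDB, n_perm: int = DEFAULT_N_PERM,
                          seed: int = 0, alpha: float | None = None) -> pd.DataFrame:
    """Significant drugs only, sorted by |z| descending.

    Ties in |z| are broken by |set_score| descending, then drug identifier;
    the returned table is the per-sub-signature "drug list" of the ensemble
    stage and carries 1-based ranks.
    """
    res = all_drug_connections(sig, db, n_perm=n_perm, seed=seed, alpha=alpha)
    sig_only = res[res["significant"]].copy()
    sig_only["_abs_z"] = sig_only["z_score"].abs()
    sig_only["_abs_s"] = sig_only["set_score"].abs()
    sig_only = sig_only.sort_values(["_abs_z", "_abs_s", "drug"],
                                    ascending=[False, False, True], kind="mergesort")
    sig_only = sig_only.drop(columns=["_abs_z", "_abs_s"]).reset_index(drop=True)
    sig_only["rank"] = np.arange(1, len(sig_only) + 1)
    return sig_only
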