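"""Core in-memory containers for the connectivity-mapping pipeline.

Tabular results are plain pandas DataFrames with documented column sets;
the classes here wrap the few structures that carry extra invariants
(expression matrices with group labels, signed signatures, signed-rank
reference profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

#: Group labels for the mutation contrast.
MT = "MT"
WT = "WT"

# Column sets of the tabular results (written as TSV by gecmap.io).
DIFF_COLUMNS = ["probe", "p_value", "log_ratio", "fold_change", "sign"]
RANKED_COLUMNS = ["probe", "sign", "p_value", "log_ratio", "rank"]
SIGNATURE_COLUMNS = ["probe", "total_score", "sign"]
CONNECTION_COLUMNS = ["drug", "set_score", "z_score", "p_value", "significant",
                      "n_instances"]
DRUGSCORE_COLUMNS = ["Drug", "Replicates", "Sumscore", "Meanscore",
                     "absMeanscore", "Rank"]
ENRICHMENT_COLUMNS = ["label", "population_size", "successes_in_population",
                      "draws", "observed", "p_value"]
CONTRIBUTION_COLUMNS = ["probe", "mean_signed_rank", "regulation",
                        "contribution", "contribution_normalized",
                        "contributive"]
SENSITIVITY_COLUMNS = ["cell_line", "disease_label", "kras_status",
                       "copy_number", "drug", "sensitivity_value", "metric"]
DIRECTION_COLUMNS = ["drug", "mean_MT", "mean_WT", "more_sensitive_in_MT",
                     "n_MT", "n_WT"]


@dataclass
class ExpressionDataset:
    """A probes x samples intensity matrix (linear scale) with MT/WT labels.

    Parameters
    ----------
    probe_ids : array of unique probe identifiers (rows).
    sample_ids : array of unique sample identifiers (columns).
    intensities : 2-D float array, shape (n_probes, n_samples), non-negative,
        linear-scale intensities (e.g. MAS5-style summarised values).
    groups : array of ``"MT"``/``"WT"`` per sample.
    name : optional dataset label (e.g. an accession-style identifier).
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    intensities: np.ndarray
    groups: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise InputError(f"{self.name or 'dataset'}: duplicate probe identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError(f"{self.name or 'dataset'}: duplicate sample identifiers")
        if self.intensities.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise InputError(
                f"{self.name or 'dataset'}: intensity matrix shape "
                f"{self.intensities.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples")
        if len(self.groups) != len(self.sample_ids):
            raise InputError(f"{self.name or 'dataset'}: one group label per sample required")
        bad = set(self.groups) - {MT, WT}
        if bad:
            raise InputError(f"{self.name or 'dataset'}: unknown group labels {sorted(bad)}")
        for g in (MT, WT):
            if int(np.sum(self.groups == g)) < 2:
                raise InputError(f"{self.name or 'dataset'}: group {g} has <2 samples")
        if np.any(self.intensities < 0) or not np.all(np.isfinite(self.intensities)):
            raise InputError(f"{self.name or 'dataset'}: intensities must be finite and >= 0")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def group_matrix(self, group: str) -> np.ndarray:
        """Sub-matrix of intensity columns belonging to one group."""
        return self.intensities[:, self.groups == group]


@dataclass
class RankedGeneList:
    """Ordered significant genes from one dataset.

    ``table`` has columns probe, sign, p_value, log_ratio, rank (1-based,
    rank 1 = most significant), sorted by (p asc, |log_ratio| desc, probe asc).
    ``n_tested`` records how many probes entered the underlying test (the
    ``n`` of the p < 1/n selection rule).
    """

    table: pd.DataFrame
    n_tested: int
    name: str = ""

    @property
    def M(self) -> int:
        """List length (the M of the (M - i + 1)/M rank score)."""
        return len(self.table)


@dataclass
class CombinedSignature:
    """Signed combined query signature, ordered by |total_score| descending.

    ``table`` has columns probe, total_score, sign; all total scores are
    non-zero and sign = sign(total_score).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.table) and np.any(self.table["total_score"].to_numpy() == 0):
            raise InputError("combined signature contains zero total scores")

    @property
    def L(self) -> int:
        return len(self.table)

    @property
    def probes(self) -> np.ndarray:
        return self.table["probe"].to_numpy(dtype=object)

    @property
    def signs(self) -> np.ndarray:
        return self.table["sign"].to_numpy(dtype=int)


class SubSignatureSeries:
    """The L nested prefixes (top-1 ... top-L genes) of a combined signature.

    Indexing is 1-based in spirit: ``series[k]`` with k in 1..L returns the
    (probes, signs) arrays of the length-k prefix.
    """

    def __init__(self, signature: CombinedSignature, max_length: int | None = None):
        if signature.L < 1:
            raise InputError("cannot derive sub-signatures from an empty signature")
        self.signature = signature
        self.L = signature.L if max_length is None else min(max_length, signature.L)
        if self.L < 1:
            raise InputError("sub-signature series must contain at least one prefix")

    def __len__(self) -> int:
        return self.L

    def prefix(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if not 1 <= k <= self.L:
            raise InputError(f"prefix length {k} outside 1..{self.L}")
        return self.signature.probes[:k], self.signature.signs[:k]

    def __iter__(self):
        for k in range(1, self.L + 1):
            yield self.prefix(k)


@dataclass
class ReferenceDB:
    """Reference database of drug treatment-instance signed-rank profiles.

    Every instance profile assigns each probe of the shared universe a signed
    rank: magnitudes are exactly a permutation of 1..N (N = probe universe
    size, magnitude N = most differentially expressed) and signs are +/-1.

    Attributes
    ----------
    probe_ids : array of N probe identifiers (the shared universe).
    signed_ranks : int array, shape (n_instances, N).
    instance_drugs : array of drug identifiers, one per instance row.
    instance_ids : array of unique instance identifiers.
    drug_meta : DataFrame with columns drug, theme, replicates.
    """

    probe_ids: np.ndarray
    signed_ranks: np.ndarray
    instance_drugs: np.ndarray
    instance_ids: np.ndarray
    drug_meta: pd.DataFrame
    _probe_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.signed_ranks = np.asarray(self.signed_ranks)
        self.instance_drugs = np.asarray(self.instance_drugs, dtype=object)
        self.instance_ids = np.asarray(self.instance_ids, dtype=object)
        n_inst, n_probes = self.signed_ranks.shape
        if n_probes != len(self.probe_ids):
            raise InputError("signed-rank matrix width does not match probe universe")
        if len(self.instance_drugs) != n_inst or len(self.instance_ids) != n_inst:
            raise InputError("per-instance metadata length mismatch")
        if len(set(self.instance_ids)) != n_inst:
            raise InputError("duplicate instance identifiers")
        counts = pd.Series(self.instance_drugs).value_counts()
        meta_drugs = set(self.drug_meta["drug"])
        if set(counts.index) != meta_drugs:
            raise InputError("drug metadata does not match instance drugs")
        if (counts < 1).any():
            raise InputError("every drug requires >=1 treatment-instance profile")
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def N(self) -> int:
        """Probe universe size."""
        return len(self.probe_ids)

    @property
    def D(self) -> int:
        """Number of drugs (the D of the p <= 1/D significance rule)."""
        return len(self.drug_meta)

    @property
    def drugs(self) -> np.ndarray:
        return self.drug_meta["drug"].to_numpy(dtype=object)

    def validate_ranks(self) -> None:
        """Check the signed-rank invariant (magnitude multiset = {1..N})."""
        mags = np.sort(np.abs(self.signed_ranks), axis=1)
        if not np.array_equal(mags, np.tile(np.arange(1, self.N + 1),
                                            (self.signed_ranks.shape[0], 1))):
            raise InputError("profile magnitudes are not a permutation of 1..N")

    def probe_columns(self, probes: np.ndarray) -> np.ndarray:
        """Column indices of the given probes; missing probes are an error."""
        missing = [p for p in probes if p not in self._probe_index]
        if missing:
            raise InputError(
                "signature probes absent from reference profiles: "
                + ", ".join(map(str, missing[:10]))
                + ("..." if len(missing) > 10 else ""))
        return np.array([self._probe_index[p] for p in probes], dtype=int)

    def instances_of(self, drug_id: str) -> np.ndarray:
        """Row indices of a drug's treatment instances."""
        rows = np.flatnonzero(self.instance_drugs == drug_id)
        if len(rows) == 0:
            raise InputError(f"drug {drug_id!r} not in reference database")
        return rows


@dataclass
class ConnectionResult:
    """Per-drug connectivity outcome against one query signature."""

    drug_id: str
    set_score: float
    z_score: float
    p_value: float
    significant: bool
    instance_scores: np.ndarray

    @property
    def n_instances(self) -> int:
        return len(self.instance_scores)
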