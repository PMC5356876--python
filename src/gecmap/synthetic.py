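"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates, at a configurable scale, the study design the pipeline consumes:
several patient expression cohorts split into KRAS-mutant and wild-type
groups with a common set of planted differentially expressed probes; a
reference database of drug treatment-instance profiles encoded as signed
ranks, with planted "reverser" drugs whose profiles oppose the planted
signature; drug-class (theme) labels; pathway sets; and a cell-line drug
screen in which planted drugs are more potent in mutant lines.

The expression noise model is log2-normal per probe and homoscedastic
within probe, so the power of the downstream t-test selection has a
closed form and can be checked independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MT, WT, SENSITIVITY_COLUMNS, ExpressionDataset, ReferenceDB
from .errors import ConfigurationError
from .utils import derive_seed as _derive_seed

#: Theme label of the planted reverser drug class (ARB analogue).
REVERSER_THEME = "ARB-like"
#: Background theme labels for non-planted drugs.
OTHER_THEMES = ("beta-blocker-like", "statin-like", "antibiotic-like", "unclassified")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    The defaults emulate the study conditions at a scale suitable for a
    workstation: 3 cohorts with the study's group sizes (29/33, 30/40,
    217/328 mutant/wild-type samples), a 2000-probe universe standing in
    for the 22268-probe platform, and 200 drugs standing in for the 1354
    FDA-approved compounds. ``full_scale()`` restores the full universe.
    """

    n_probes: int = 2000
    n_datasets: int = 3
    samples_per_group: tuple[tuple[int, int], ...] = ((29, 33), (30, 40), (217, 328))
    n_true_de: int = 100
    effect_log2: float = 1.0
    noise_sd: float = 0.5
    frac_shared: float = 0.8
    baseline_log2_range: tuple[float, float] = (6.0, 10.0)
    n_drugs: int = 200
    replicates_range: tuple[int, int] = (3, 20)
    n_reversers: int = 5
    reverser_strength: float = 0.9
    theme_assignments: dict[str, str] | None = None
    n_extra_theme_drugs: int = 2
    mt_cell_lines: int = 24
    wt_cell_lines: int = 25
    screen_shift: float = -0.1
    screen_noise_sd: float = 0.1
    n_pathways: int = 20
    pathway_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes", "n_datasets", "n_true_de", "n_drugs",
                     "mt_cell_lines", "wt_cell_lines", "n_pathways",
                     "pathway_size"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_reversers < 0:
            raise ConfigurationError("n_reversers must be >= 0")
        if self.n_true_de > self.n_probes:
            raise ConfigurationError("n_true_de exceeds n_probes")
        if self.n_reversers > self.n_drugs:
            raise ConfigurationError("n_reversers exceeds n_drugs")
        if len(self.samples_per_group) != self.n_datasets:
            raise ConfigurationError(
                "samples_per_group must supply one (MT, WT) pair per dataset")
        for pair in self.samples_per_group:
            if min(pair) < 2:
                raise ConfigurationError("samples_per_group entries must be >= 2")
        if self.effect_log2 < 0:
            raise ConfigurationError("effect_log2 must be >= 0")
        if self.noise_sd <= 0 or self.screen_noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.frac_shared <= 1.0:
            raise ConfigurationError("frac_shared must lie in [0, 1]")
        if not 0.0 <= self.reverser_strength <= 1.0:
            raise ConfigurationError("reverser_strength must lie in [0, 1]")
        lo, hi = self.replicates_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                "replicates_range must be a positive interval (lo >= 1, hi >= lo)")

    def probe_names(self) -> np.ndarray:
        width = len(str(self.n_probes))
        return np.array([f"probe_{i:0{width}d}" for i in range(1, self.n_probes + 1)],
                        dtype=object)

    def drug_names(self) -> np.ndarray:
        width = len(str(self.n_drugs))
        return np.array([f"drug_{i:0{width}d}" for i in range(1, self.n_drugs + 1)],
                        dtype=object)


def full_scale(**overrides) -> SimulationConfig:
    """The full-size preset: 22268 probes, 1354 drugs (benchmark use)."""
    params = dict(n_probes=22268, n_drugs=1354, n_true_de=248,
                  replicates_range=(10, 178))
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery testing.

    ``planted_signs`` maps each planted probe to its regulation sign in the
    mutant group (+1 up, -1 down); ``shared_probes`` are those planted in
    every dataset. ``reverser_drugs`` oppose the planted signature in the
    reference database; ``sensitive_drugs`` carry the negative MT-WT
    sensitivity shift in the screen.
    """

    planted_signs: dict[str, int]
    shared_probes: tuple[str, ...]
    dataset_probes: tuple[tuple[str, ...], ...]
    reverser_drugs: tuple[str, ...] = ()
    sensitive_drugs: tuple[str, ...] = ()

    @property
    def planted_probes(self) -> set[str]:
        return set(self.planted_signs)


def gen_expression_datasets(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate the expression cohorts and record the planted truth.

    Each probe has a baseline log2 mean drawn uniformly from
    ``baseline_log2_range``; samples add N(0, noise_sd^2) log2 noise.
    Planted probes shift the mutant-group mean by +/- ``effect_log2``
    (sign drawn per probe). A ``frac_shared`` fraction of planted probes
    is planted in every dataset; the remainder are assigned round-robin to
    single datasets. Returned intensities are on the linear scale (2^x).
    """
    rng = np.random.default_rng(config.seed)
    probes = config.probe_names()

    planted_idx = rng.choice(config.n_probes, size=config.n_true_de, replace=False)
    signs = rng.choice([-1, 1], size=config.n_true_de)
    n_shared = int(round(config.frac_shared * config.n_true_de))
    shared = planted_idx[:n_shared]
    rest = planted_idx[n_shared:]

    per_dataset: list[np.ndarray] = []
    for d in range(config.n_datasets):
        own = rest[d::config.n_datasets]
        per_dataset.append(np.concatenate([shared, own]))

    sign_of = dict(zip(planted_idx, signs))
    baselines = rng.uniform(*config.baseline_log2_range, size=config.n_probes)

    datasets = []
    for d, (n_mt, n_wt) in enumerate(config.samples_per_group):
        n_samples = n_mt + n_wt
        log2 = baselines[:, None] + rng.normal(
            0.0, config.noise_sd, size=(config.n_probes, n_samples))
        for idx in per_dataset[d]:
            log2[idx, :n_mt] += sign_of[idx] * config.effect_log2
        groups = np.array([MT] * n_mt + [WT] * n_wt, dtype=object)
        sample_ids = np.array(
            [f"ds{d + 1}_s{j + 1:03d}" for j in range(n_samples)], dtype=object)
        datasets.append(ExpressionDataset(
            probe_ids=probes, sample_ids=sample_ids,
            intensities=np.power(2.0, log2), groups=groups,
            name=f"synthetic_ds{d + 1}"))

    truth = GroundTruth(
        planted_signs={probes[i]: int(sign_of[i]) for i in planted_idx},
        shared_probes=tuple(probes[i] for i in shared),
        dataset_probes=tuple(tuple(probes[i] for i in idx) for idx in per_dataset),
    )
    return datasets, truth


def _default_themes(config: SimulationConfig, drugs: np.ndarray,
                    reversers: np.ndarray, rng: np.random.Generator) -> dict[str, str]:
    """Reversers plus a few decoys share the planted theme; the rest are
    spread over background themes (emulates a small drug class of which
    most members surface among the top candidates)."""
    themes = {}
    non_rev = [d for d in drugs if d not in set(reversers)]
    extra = rng.choice(len(non_rev), size=min(config.n_extra_theme_drugs, len(non_rev)),
                       replace=False)
    extra_set = {non_rev[i] for i in extra}
    for d in drugs:
        if d in set(reversers) or d in extra_set:
            themes[d] = REVERSER_THEME
        else:
            themes[d] = OTHER_THEMES[rng.integers(len(OTHER_THEMES))]
    return themes


def gen_reference_db(config: SimulationConfig, truth: GroundTruth) -> ReferenceDB:
    """Simulate the signed-rank reference database with planted reversers.

    Every treatment instance is an independent uniform signed permutation of
    magnitudes 1..N over the probe universe. For reverser drugs, each planted
    probe is moved (independently, with probability ``reverser_strength``)
    into the top-magnitude block with sign opposite to its planted
    regulation, so their profiles anti-align with the planted signature;
    strength 1 gives a connection score of exactly -1 for the planted
    signature. Replicate counts per drug are drawn uniformly from
    ``replicates_range``.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "refdb"))
    probes = config.probe_names()
    probe_index = {p: i for i, p in enumerate(probes)}
    drugs = config.drug_names()
    N = config.n_probes

    planted = [(probe_index[p], s) for p, s in sorted(truth.planted_signs.items())]
    missing = truth.planted_probes - set(probes)
    if missing:
        raise ConfigurationError(
            "probe universe does not cover planted probes: " + ", ".join(sorted(missing)[:5]))

    reversers = drugs[:config.n_reversers]
    lo, hi = config.replicates_range
    replicates = rng.integers(lo, hi + 1, size=config.n_drugs)

    rows, instance_drugs, instance_ids = [], [], []
    for drug, n_rep in zip(drugs, replicates):
        is_rev = drug in set(reversers)
        for r in range(n_rep):
            perm = rng.permutation(N) + 1          # magnitudes
            prof_signs = rng.choice([-1, 1], size=N)
            if is_rev and planted:
                _plant_reverser(perm, prof_signs, planted,
                                config.reverser_strength, rng)
            rows.append(perm * prof_signs)
            instance_drugs.append(drug)
            instance_ids.append(f"{drug}_inst{r + 1:03d}")

    truth.reverser_drugs = tuple(reversers)
    themes = config.theme_assignments or _default_themes(config, drugs, reversers, rng)
    meta = pd.DataFrame({
        "drug": drugs,
        "theme": [themes.get(d, "unclassified") for d in drugs],
        "replicates": replicates,
    })
    return ReferenceDB(
        probe_ids=probes,
        signed_ranks=np.asarray(rows, dtype=np.int64),
        instance_drugs=np.asarray(instance_drugs, dtype=object),
        instance_ids=np.asarray(instance_ids, dtype=object),
        drug_meta=meta,
    )


def _plant_reverser(perm: np.ndarray, prof_signs: np.ndarray,
                    planted: list[tuple[int, int]], strength: float,
                    rng: np.random.Generator) -> None:
    """Swap planted probes into the top-magnitude block, flipping signs.

    Works in place on one instance's magnitude permutation and sign vector.
    The k-th planted probe (with probability ``strength``) exchanges
    magnitudes with whichever probe currently holds magnitude N - k, and
    takes the sign opposite to its planted regulation.
    """
    N = len(perm)
    pos_of_mag = np.empty(N + 1, dtype=np.int64)
    pos_of_mag[perm] = np.arange(N)
    take = rng.random(len(planted)) < strength
    next_mag = N
    for (idx, sign), chosen in zip(planted, take):
        if not chosen:
            continue
        holder = pos_of_mag[next_mag]
        old_mag = perm[idx]
        perm[holder], perm[idx] = old_mag, next_mag
        pos_of_mag[old_mag], pos_of_mag[next_mag] = holder, idx
        prof_signs[idx] = -sign
        next_mag -= 1


def gen_sensitivity_screen(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate the cell-line drug screen (AUC semantics: smaller = more
    sensitive).

    Baseline sensitivity per (line, drug) is N(0.5, screen_noise_sd^2);
    drugs planted as effective in mutant lines add ``screen_shift``
    (negative) to the mutant-group mean. One wild-type line receives a
    copy number of 9 to exercise the genetic-outlier filter; all others
    are assigned copy number 2.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "screen"))
    drugs = config.drug_names()
    sensitive = set(drugs[:config.n_reversers])
    truth.sensitive_drugs = tuple(sorted(sensitive))

    lines = ([f"MTline_{i + 1:02d}" for i in range(config.mt_cell_lines)]
             + [f"WTline_{i + 1:02d}" for i in range(config.wt_cell_lines)])
    status = [MT] * config.mt_cell_lines + [WT] * config.wt_cell_lines
    copy_number = {ln: 2.0 for ln in lines}
    outlier = f"WTline_{config.wt_cell_lines:02d}"
    copy_number[outlier] = 9.0

    records = []
    for drug in drugs:
        values = rng.normal(0.5, config.screen_noise_sd, size=len(lines))
        if drug in sensitive:
            values[:config.mt_cell_lines] += config.screen_shift
        for ln, st, v in zip(lines, status, values):
            records.append((ln, "large intestine carcinoma", st,
                            copy_number[ln], drug, float(v), "AUC"))
    table = pd.DataFrame(records, columns=SENSITIVITY_COLUMNS)
    return table


def gen_pathways(config: SimulationConfig, truth: GroundTruth) -> dict[str, list[str]]:
    """Pathway sets (GMT-shaped dict) with one pathway holding all planted
    probes and the rest drawn uniformly from the universe."""
    rng = np.random.default_rng(_derive_seed(config.seed, "pathways"))
    probes = config.probe_names()
    pathways = {"PLANTED_PATHWAY": sorted(truth.planted_probes)}
    for i in range(config.n_pathways - 1):
        members = rng.choice(config.n_probes, size=config.pathway_size, replace=False)
        pathways[f"pathway_{i + 1:02d}"] = sorted(probes[j] for j in members)
    return pathways


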