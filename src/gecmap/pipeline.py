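"""End-to-end pipeline: differential expression -> combined signature ->
nested sub-signature ensemble -> drug prioritisation -> enrichment,
contributive genes and (optionally) drug-screen validation.

Every stage writes its result table under the output directory and logs
its parameters and counts; re-running with an identical configuration
and seed is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io
from .contributive import contributive_set, overlap_contributive, probe_contributions
from .datatypes import CombinedSignature
from .diffexpr import DEFAULT_FC_THRESHOLD, differential_stats, select_significant
from .ensemble import combine_drug_lists, run_ensemble, score_trajectories
from .enrichment import (DEFAULT_TOP_K, drug_theme_enrichment,
                         pathway_overrepresentation)
from .errors import ConfigurationError
from .signature import combine_signatures, make_subsignatures
from .validation import (DEFAULT_ABS_MEAN_THRESHOLD, DEFAULT_COPY_NUMBER_MAX,
                         agreement_rate)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``expression`` lists (matrix, group-table) path pairs, one per cohort.
    ``seed`` is mandatory: every stochastic stage derives its seed from it.
    ``max_prefixes`` truncates the sub-signature series for scaled-down
    runs (None = all L prefixes).
    """

    expression: list[tuple[str, str]] = field(default_factory=list)
    refdb_dir: str = ""
    out_dir: str = "gecmap_out"
    pathways: str | None = None
    theme_map: str | None = None
    screen: str | None = None
    alpha: float | None = None
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    top_k: int = DEFAULT_TOP_K
    abs_mean_threshold: float = DEFAULT_ABS_MEAN_THRESHOLD
    copy_number_max: float = DEFAULT_COPY_NUMBER_MAX
    disease_filter: str | None = None
    n_perm: int = 10_000
    seed: int | None = None
    max_prefixes: int | None = None
    equal_var: bool = False
    contrib_drugs: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory (stochastic stages)")
        if not self.expression:
            raise ConfigurationError("expression: at least one cohort required")
        if not self.refdb_dir:
            raise ConfigurationError("refdb_dir is required")
        if self.fc_threshold < 1.0:
            raise ConfigurationError("fc_threshold must be >= 1")
        if self.alpha is not None and not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be positive")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full procedure; returns the artifact bundle as a dict.

    Bundle keys: ranked_lists, signature, drug_lists, drug_table,
    trajectories, and (when the corresponding inputs are configured)
    theme_enrichment, pathway_enrichment, contributions, overlap,
    agreement_rate, direction_table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    datasets = [io.read_expression(m, g) for m, g in config.expression]
    db = io.read_reference_db(config.refdb_dir)
    logger.info("inputs: %d cohorts, reference database of %d drugs / %d "
                "instances over %d probes", len(datasets), db.D,
                len(db.instance_ids), db.N)

    ranked = []
    for ds in datasets:
        diff = differential_stats(ds, equal_var=config.equal_var)
        sel = select_significant(diff, alpha=config.alpha,
                                 fc_threshold=config.fc_threshold, name=ds.name)
        io.write_table(diff, out / f"diff_{ds.name}.tsv")
        io.write_table(sel.table, out / f"ranked_{ds.name}.tsv")
        logger.info("%s: %d/%d probes significant (alpha=%s, FC>%g)", ds.name,
                    sel.M, sel.n_tested,
                    "1/n" if config.alpha is None else config.alpha,
                    config.fc_threshold)
        ranked.append(sel)

    signature = combine_signatures(ranked)
    io.write_signature(signature, out / "signature.tsv",
                       out / "signature_scores.tsv")
    logger.info("combined signature: L = %d genes", signature.L)

    series = make_subsignatures(signature, max_length=config.max_prefixes)
    drug_lists = run_ensemble(series, db, n_perm=config.n_perm,
                              seed=config.seed)
    drug_table = combine_drug_lists(drug_lists, db=db)
    io.write_table(drug_table, out / "drug_table.tsv")
    trajectories = score_trajectories(
        drug_lists, drugs=list(drug_table.head(5)["Drug"]))
    io.write_table(trajectories, out / "trajectories.tsv")
    logger.info("ensemble: %d prefixes (n_perm=%d, seed=%d) -> %d drugs with "
                "non-zero sum score", len(series), config.n_perm, config.seed,
                len(drug_table))

    bundle: dict = {"ranked_lists": ranked, "signature": signature,
                    "drug_lists": drug_lists, "drug_table": drug_table,
                    "trajectories": trajectories}

    if config.theme_map is not None and len(drug_table) > 0:
        themes = io.read_theme_map(config.theme_map)
        top_k = min(config.top_k, len(drug_table))
        theme_table = drug_theme_enrichment(drug_table, themes, top_k=top_k)
        io.write_table(theme_table, out / "theme_enrichment.tsv")
        logger.info("theme enrichment over top %d drugs: best %r (p=%.3g)",
                    top_k, theme_table.iloc[0]["label"],
                    theme_table.iloc[0]["p_value"])
        bundle["theme_enrichment"] = theme_table

    if config.pathways is not None:
        pathways = io.read_gmt(config.pathways)
        in_any = set().union(*pathways.values())
        background = {p for p in datasets[0].probe_ids if p in in_any}
        pathway_table = pathway_overrepresentation(signature, pathways,
                                                   background)
        io.write_table(pathway_table, out / "pathway_enrichment.tsv")
        logger.info("pathway over-representation: %d pathways, background %d "
                    "probes", len(pathway_table), len(background))
        bundle["pathway_enrichment"] = pathway_table

    if config.contrib_drugs > 0 and len(drug_table) >= 2:
        negative = drug_table[drug_table["Meanscore"] < 0]
        focus = list(negative.head(min(config.contrib_drugs, 4))["Drug"])
        contributions = {}
        for drug in focus:
            table = probe_contributions(db, drug, signature)
            io.write_table(table, out / f"contrib_{drug}.tsv")
            contributions[drug] = table
        bundle["contributions"] = contributions
        if len(focus) >= 2:
            sets = {d: contributive_set(db, d, signature) for d in focus}
            overlap = overlap_contributive(sets)
            io.write_table(overlap["regions"], out / "contrib_overlap.tsv")
            logger.info("contributive genes: %d common to all %d top "
                        "reversers", len(overlap["core"]), len(focus))
            bundle["overlap"] = overlap

    if config.screen is not None and len(drug_table) > 0:
        screen = io.read_screen(config.screen)
        fraction, direction = agreement_rate(
            drug_table, screen, abs_mean_threshold=config.abs_mean_threshold,
            disease_filter=config.disease_filter,
            copy_number_max=config.copy_number_max)
        io.write_table(direction, out / "direction_of_action.tsv")
        logger.info("direction-of-action agreement: %.0f%% of %d evaluated "
                    "drugs more sensitive in MT lines", 100 * fraction,
                    len(direction))
        bundle["agreement_rate"] = fraction
        bundle["direction_table"] = direction

    return bundle


def make_signature(config: PipelineConfig) -> CombinedSignature:
    """Signature-only shortcut: differential expression and combination."""
    datasets = [io.read_expression(m, g) for m, g in config.expression]
    ranked = [select_significant(
        differential_stats(ds, equal_var=config.equal_var),
        alpha=config.alpha, fc_threshold=config.fc_threshold, name=ds.name)
        for ds in datasets]
    return combine_signatures(ranked)
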