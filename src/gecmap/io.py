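"""Tab-separated readers and writers for every on-disk format.

All formats are plain text with header rows; write followed by read is
the identity on the data model, and malformed input is rejected with
the offending file (and where possible the line) named. The reference
database lives in a directory: one signed-rank table per drug (probe
column plus one column per treatment instance) and a drug-metadata
table (drug, theme, replicates).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (SENSITIVITY_COLUMNS, CombinedSignature,
                        ExpressionDataset, ReferenceDB)
from .errors import InputError

DRUG_META_FILE = "drug_metadata.tsv"


# -- expression matrices ----------------------------------------------------

def write_expression(ds: ExpressionDataset, matrix_path: str | Path,
                     groups_path: str | Path) -> None:
    """Expression matrix (probes x samples) and two-column group table."""
    pd.DataFrame(ds.intensities, index=pd.Index(ds.probe_ids, name="probe"),
                 columns=ds.sample_ids).to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample": ds.sample_ids, "group": ds.groups}).to_csv(
        groups_path, sep="\t", index=False)


def read_expression(matrix_path: str | Path, groups_path: str | Path,
                    name: str = "") -> ExpressionDataset:
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        intensities = matrix.to_numpy(dtype=float)
    except ValueError as exc:
        raise InputError(f"{matrix_path}: non-numeric intensity value ({exc})")
    groups = pd.read_csv(groups_path, sep="\t")
    if list(groups.columns) != ["sample", "group"]:
        raise InputError(f"{groups_path}: expected columns 'sample', 'group'")
    group_of = dict(zip(groups["sample"], groups["group"]))
    missing = [s for s in matrix.columns if s not in group_of]
    if missing:
        raise InputError(f"{groups_path}: no group label for sample(s) "
                         + ", ".join(map(str, missing[:5])))
    return ExpressionDataset(
        probe_ids=matrix.index.to_numpy(dtype=object),
        sample_ids=matrix.columns.to_numpy(dtype=object),
        intensities=intensities,
        groups=np.array([group_of[s] for s in matrix.columns], dtype=object),
        name=name or Path(matrix_path).stem)


# -- signed signatures ------------------------------------------------------

def write_signature(sig: CombinedSignature, path: str | Path,
                    scores_path: str | Path | None = None) -> None:
    """Two-column signed signature (probe TAB +/-), ordered; optional
    full scores table alongside."""
    with open(path, "w") as fh:
        fh.write("probe\tsign\n")
        for probe, sign in zip(sig.probes, sig.signs):
            fh.write(f"{probe}\t{'+' if sign > 0 else '-'}\n")
    if scores_path is not None:
        sig.table.to_csv(scores_path, sep="\t", index=False)


def read_signature(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a signed two-column signature as (probes, signs) arrays."""
    probes, signs = [], []
    with open(path) as fh:
        header = fh.readline()
        if header.strip().split("\t") != ["probe", "sign"]:
            raise InputError(f"{path}: expected header 'probe<TAB>sign'")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 or fields[1] not in {"+", "-", "+1", "-1"}:
                raise InputError(f"{path}:{lineno}: malformed signature row "
                                 f"{line.rstrip()!r}")
            probes.append(fields[0])
            signs.append(1 if fields[1].lstrip("+") in {"", "1"} else -1)
    if len(set(probes)) != len(probes):
        raise InputError(f"{path}: duplicate probes in signature")
    return np.array(probes, dtype=object), np.array(signs, dtype=int)


# -- reference database -----------------------------------------------------

def write_reference_db(db: ReferenceDB, directory: str | Path) -> None:
    """One signed-rank table per drug plus the drug-metadata table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    db.drug_meta.to_csv(directory / DRUG_META_FILE, sep="\t", index=False)
    for drug in db.drugs:
        rows = db.instances_of(drug)
        cols = {"probe": db.probe_ids}
        for r in rows:
            cols[str(db.instance_ids[r])] = db.signed_ranks[r]
        pd.DataFrame(cols).to_csv(directory / f"{drug}.tsv", sep="\t",
                                  index=False)


def read_reference_db(directory: str | Path, validate: bool = True) -> ReferenceDB:
    directory = Path(directory)
    meta_path = directory / DRUG_META_FILE
    if not meta_path.exists():
        raise InputError(f"{meta_path}: drug metadata table missing")
    meta = pd.read_csv(meta_path, sep="\t")
    if list(meta.columns) != ["drug", "theme", "replicates"]:
        raise InputError(f"{meta_path}: expected columns drug, theme, replicates")

    probe_ids = None
    ranks, instance_drugs, instance_ids = [], [], []
    for drug in meta["drug"]:
        path = directory / f"{drug}.tsv"
        if not path.exists():
            raise InputError(f"{path}: profile table for drug {drug!r} missing")
        table = pd.read_csv(path, sep="\t")
        if table.columns[0] != "probe":
            raise InputError(f"{path}: first column must be 'probe'")
        if probe_ids is None:
            probe_ids = table["probe"].to_numpy(dtype=object)
            if len(set(probe_ids)) != len(probe_ids):
                raise InputError(f"{path}: duplicate probe identifiers")
        elif not np.array_equal(table["probe"].to_numpy(dtype=object), probe_ids):
            raise InputError(f"{path}: probe universe differs from other profiles")
        for col in table.columns[1:]:
            try:
                vec = table[col].to_numpy(dtype=np.int64)
            except (ValueError, TypeError):
                raise InputError(f"{path}: non-integer signed rank in column {col!r}")
            ranks.append(vec)
            instance_drugs.append(drug)
            instance_ids.append(col)

    db = ReferenceDB(probe_ids=probe_ids, signed_ranks=np.asarray(ranks),
                     instance_drugs=np.asarray(instance_drugs, dtype=object),
                     instance_ids=np.asarray(instance_ids, dtype=object),
                     drug_meta=meta)
    if validate:
        db.validate_ranks()
    return db


# -- GMT pathway sets -------------------------------------------------------

def write_gmt(pathways: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: name TAB description TAB member1 TAB member2 ... Empty sets are
    skipped with a warning."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise InputError(f"{path}:{lineno}: malformed GMT row")
            name, members = fields[0], [m for m in fields[2:] if m]
            if name in pathways:
                raise InputError(f"{path}:{lineno}: duplicate pathway {name!r}")
            if not members:
                warnings.warn(f"{path}:{lineno}: empty pathway {name!r} skipped",
                              stacklevel=2)
                continue
            pathways[name] = members
    return pathways


# -- theme map, screen, generic tables --------------------------------------

def write_theme_map(themes: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(themes.items()), columns=["drug", "theme"]).to_csv(
        path, sep="\t", index=False)


def read_theme_map(path: str | Path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    if list(table.columns) != ["drug", "theme"]:
        raise InputError(f"{path}: expected columns 'drug', 'theme'")
    if table["drug"].duplicated().any():
        dupes = table.loc[table["drug"].duplicated(), "drug"].tolist()
        raise InputError(f"{path}: duplicate drug(s) in theme map: {dupes[:5]}")
    return dict(zip(table["drug"], table["theme"]))


def write_screen(screen: pd.DataFrame, path: str | Path) -> None:
    screen.to_csv(path, sep="\t", index=False)


def read_screen(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SENSITIVITY_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"{path}: missing screen column(s) {missing}")
    metrics = set(table["metric"])
    if len(metrics) > 1:
        raise InputError(f"{path}: mixed sensitivity metrics {sorted(metrics)}")
    if not np.all(np.isfinite(table["sensitivity_value"].to_numpy(dtype=float))):
        raise InputError(f"{path}: non-finite sensitivity values")
    return table[SENSITIVITY_COLUMNS]


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Generic results-table writer (TSV with header)."""
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
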