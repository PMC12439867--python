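"""Reaction table input/output.

Reactions arrive as CSV/TSV tables carrying reaction SMILES (``r1.r2>>p1.p2``),
optional atom-mapped reaction SMILES, and per-side compound identifiers (CIDs).
This module builds reaction SMILES from component lists, validates and filters
record sets (CID-based redundancy removal), and reads/writes the table dialect
the rest of the pipeline consumes.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRef",
    "ReactionRecord",
    "FilterReport",
    "build_reaction_smiles",
    "split_reaction_smiles",
    "filter_reactions",
    "read_reaction_table",
    "write_reaction_table",
    "read_queries",
    "load_column_map",
    "DEFAULT_COLUMNS",
]


class ReactionParseError(ValueError):
    """A reaction component could not be parsed as a molecule."""


@dataclass
class MoleculeRef:
    """One reaction component: canonical SMILES plus optional CID and role."""

    smiles: str
    cid: str | None = None
    role: str = "reactant"  # "reactant" | "product"

    def __post_init__(self) -> None:
        if self.role not in ("reactant", "product"):
            raise ValueError(f"invalid role {self.role!r}")


@dataclass
class ReactionRecord:
    """A single reaction row: identifiers, SMILES forms, and components."""

    rxn_id: str
    reaction_smiles: str
    reactants: list[MoleculeRef] = field(default_factory=list)
    products: list[MoleculeRef] = field(default_factory=list)
    mapped_reaction_smiles: str | None = None
    source: str = ""
    enzymatic: bool | None = None

    def __post_init__(self) -> None:
        if self.reaction_smiles.count(">>") != 1:
            raise ValueError(
                f"reaction {self.rxn_id}: reaction SMILES must contain exactly one '>>'"
            )

    @property
    def reactant_cids(self) -> list[str | None]:
        return [m.cid for m in self.reactants]

    @property
    def product_cids(self) -> list[str | None]:
        return [m.cid for m in self.products]


@dataclass
class FilterReport:
    """Counts from :func:`filter_reactions`; read = kept + dropped."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_missing_cid: int = 0
    n_dropped_duplicate: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_missing_cid + self.n_dropped_duplicate


def _parse_or_raise(smiles: str, what: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ReactionParseError(f"unparsable SMILES for {what}: {smiles!r}")
    return mol


def build_reaction_smiles(
    reactants: Sequence[str], products: Sequence[str]
) -> str:
    """Join component SMILES into ``r1.r2>>p1.p2`` form, preserving order.

    Every component must parse; empty sides are rejected.
    """
    if not reactants or not products:
        raise ValueError("empty reaction side")
    for i, smi in enumerate(reactants):
        _parse_or_raise(smi, f"reactant {i}")
    for i, smi in enumerate(products):
        _parse_or_raise(smi, f"product {i}")
    return ".".join(reactants) + ">>" + ".".join(products)


def split_reaction_smiles(reaction_smiles: str) -> tuple[list[str], list[str]]:
    """Inverse of :func:`build_reaction_smiles` (component-wise split).

    Splitting is on top-level ``.`` only; dots inside dative/complex SMILES are
    not treated specially (the pipeline's tables never quote components).
    """
    if reaction_smiles.count(">>") != 1:
        raise ValueError("reaction SMILES must contain exactly one '>>'")
    left, right = reaction_smiles.split(">>")
    return (
        [s for s in left.split(".") if s],
        [s for s in right.split(".") if s],
    )


def _cid_key(record: ReactionRecord) -> tuple | None:
    """Order-insensitive per-side CID multiset key; None if any CID missing."""
    r_cids = record.reactant_cids
    p_cids = record.product_cids
    if any(c is None or c == "" for c in r_cids + p_cids) or not r_cids or not p_cids:
        return None
    return (
        tuple(sorted(Counter(r_cids).items())),
        tuple(sorted(Counter(p_cids).items())),
    )


def filter_reactions(
    records: Sequence[ReactionRecord],
) -> tuple[list[ReactionRecord], FilterReport]:
    """Drop records with missing CIDs and CID-redundant reactions.

    Two reactions are redundant when their reactant-CID multiset and
    product-CID multiset both coincide; the first occurrence (file order) is
    kept. Records missing any reactant or product CID are dropped. Stable
    order; idempotent.
    """
    report = FilterReport(n_read=len(records))
    seen: set[tuple] = set()
    kept: list[ReactionRecord] = []
    for rec in records:
        key = _cid_key(rec)
        if key is None:
            report.n_dropped_missing_cid += 1
            logger.debug("dropping %s: missing CID", rec.rxn_id)
            continue
        if key in seen:
            report.n_dropped_duplicate += 1
            logger.debug("dropping %s: duplicate CID multisets", rec.rxn_id)
            continue
        seen.add(key)
        kept.append(rec)
    report.n_kept = len(kept)
    return kept, report


#: Default column names for reaction tables (fixture dialect).
DEFAULT_COLUMNS: dict[str, str] = {
    "rxn_id": "RXN_ID",
    "reaction_smiles": "REACTION_SMILES",
    "mapped_reaction_smiles": "MAPPED_REACTION",
    "reactant_cids": "REACTANT_CIDS",
    "product_cids": "PRODUCT_CIDS",
    "source": "SOURCE",
    "enzymatic": "ENZYMATIC",
}

#: Separator for CID lists within one table cell.
CID_SEP = ";"


def load_column_map(path: str | Path | None) -> dict[str, str]:
    """Load a YAML/JSON column-mapping config; None -> defaults."""
    if path is None:
        return dict(DEFAULT_COLUMNS)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    colmap = dict(DEFAULT_COLUMNS)
    unknown = set(user) - set(colmap)
    if unknown:
        raise KeyError(f"unknown column-map keys: {sorted(unknown)}")
    colmap.update(user)
    return colmap


def _parse_bool(val: str) -> bool | None:
    if val is None or val == "":
        return None
    return str(val).strip().lower() in ("1", "true", "yes", "y", "t")


def read_reaction_table(
    path: str | Path,
    column_map: Mapping[str, str] | str | Path | None = None,
) -> tuple[list[ReactionRecord], dict]:
    """Read a CSV/TSV reaction table into :class:`ReactionRecord` objects.

    Rows whose reaction SMILES fails to parse are skipped with a logged
    warning. Returns ``(records, read_report)`` where the report counts rows
    read, kept and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(column_map, (str, Path)) or column_map is None:
        colmap = load_column_map(column_map)
    else:
        colmap = dict(DEFAULT_COLUMNS, **dict(column_map))

    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    records: list[ReactionRecord] = []
    n_read = n_skipped = 0
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty table")
        for required in ("rxn_id", "reaction_smiles"):
            if colmap[required] not in reader.fieldnames:
                raise KeyError(
                    f"{path}: missing configured column {colmap[required]!r}"
                )
        for row in reader:
            n_read += 1
            rxn_id = row[colmap["rxn_id"]]
            rsmi = row[colmap["reaction_smiles"]]
            try:
                r_smis, p_smis = split_reaction_smiles(rsmi)
                if not r_smis or not p_smis:
                    raise ReactionParseError("empty reaction side")
                for smi in r_smis + p_smis:
                    _parse_or_raise(smi, f"component of {rxn_id}")
            except (ValueError, ReactionParseError) as exc:
                n_skipped += 1
                logger.warning("skipping row %s: %s", rxn_id, exc)
                continue
            r_cids = _split_cids(row.get(colmap["reactant_cids"], ""), len(r_smis))
            p_cids = _split_cids(row.get(colmap["product_cids"], ""), len(p_smis))
            records.append(
                ReactionRecord(
                    rxn_id=rxn_id,
                    reaction_smiles=rsmi,
                    reactants=[
                        MoleculeRef(s, c, "reactant")
                        for s, c in zip(r_smis, r_cids)
                    ],
                    products=[
                        MoleculeRef(s, c, "product")
                        for s, c in zip(p_smis, p_cids)
                    ],
                    mapped_reaction_smiles=(
                        row.get(colmap["mapped_reaction_smiles"]) or None
                    ),
                    source=row.get(colmap["source"], "") or "",
                    enzymatic=_parse_bool(row.get(colmap["enzymatic"], "")),
                )
            )
    report = {"n_read": n_read, "n_kept": len(records), "n_skipped": n_skipped}
    return records, report


def _split_cids(cell: str | None, n: int) -> list[str | None]:
    if cell is None or cell == "":
        return [None] * n
    parts = [p.strip() or None for p in str(cell).split(CID_SEP)]
    if len(parts) < n:
        parts += [None] * (n - len(parts))
    return parts[:n]


def write_reaction_table(
    records: Iterable[ReactionRecord],
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records back to CSV/TSV in the same dialect the reader accepts."""
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS, **(dict(column_map) if column_map else {}))
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    fields = [
        colmap["rxn_id"],
        colmap["reaction_smiles"],
        colmap["mapped_reaction_smiles"],
        colmap["reactant_cids"],
        colmap["product_cids"],
        colmap["source"],
        colmap["enzymatic"],
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(fields)
        for rec in records:
            writer.writerow(
                [
                    rec.rxn_id,
                    rec.reaction_smiles,
                    rec.mapped_reaction_smiles or "",
                    CID_SEP.join(c or "" for c in rec.reactant_cids),
                    CID_SEP.join(c or "" for c in rec.product_cids),
                    rec.source,
                    "" if rec.enzymatic is None else str(rec.enzymatic).lower(),
                ]
            )


def read_queries(path: str | Path, smiles_column: str = "SMILES") -> list[tuple[str, str]]:
    """Read query compounds from a .smi or CSV/TSV file.

    Returns ``(query_id, smiles)`` pairs; unparsable rows are skipped with a
    warning. For ``.smi``, each line is ``SMILES [identifier]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[tuple[str, str]] = []
    if path.suffix.lower() in (".smi", ".smiles", ".txt"):
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            qid = parts[1].strip() if len(parts) > 1 else f"Q{i + 1}"
            if Chem.MolFromSmiles(smi) is None:
                logger.warning("skipping query %s: unparsable SMILES", qid)
                continue
            out.append((qid, smi))
    else:
        delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise KeyError(f"{path}: missing column {smiles_column!r}")
            id_col = next(
                (c for c in ("QUERY_ID", "ID", "CID") if c in reader.fieldnames),
                None,
            )
            for i, row in enumerate(reader):
                smi = row[smiles_column]
                qid = row[id_col] if id_col else f"Q{i + 1}"
                if Chem.MolFromSmiles(smi) is None:
                    logger.warning("skipping query %s: unparsable SMILES", qid)
                    continue
                out.append((qid, smi))
    return out
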