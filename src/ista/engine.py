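"""Transformation-product enumeration for query compounds.

A query is screened against the reactive-substructure database to find the
applicable templates; each matching template is applied with RDKit's
``RunReactants``; every successful embedding is reduced to its principal
product — the largest covalent fragment of the embedding's product set, which
discards leaving groups and salts — canonicalized, and deduplicated by the
InChIKey of that fragment. Products identical to the parent are excluded.
One transformation round is performed (no metabolite-of-metabolite chaining
by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

logger = logging.getLogger(__name__)

__all__ = [
    "QueryCompound",
    "dedup_key",
    "screen_templates",
    "apply_template",
    "transform",
    "annotate_known",
    "load_snapshot",
    "PRODUCT_COLUMNS",
]

PRODUCT_COLUMNS = [
    "query_id",
    "query_smiles",
    "product_smiles",
    "dedup_key",
    "rxn_id",
    "template_id",
    "known_cid",
]

_LIST_SEP = "|"


@dataclass
class QueryCompound:
    """A validated query structure."""

    query_id: str
    smiles: str
    cid: str | None = None
    class_label: str | None = None

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(
                f"query {self.query_id}: unparsable SMILES {self.smiles!r}"
            )
        self.mol = mol
        self.smiles = Chem.MolToSmiles(mol)


def largest_fragment(mol_or_smiles: Chem.Mol | str) -> str:
    """Canonical SMILES of the largest covalent fragment.

    Ties on heavy-atom count break on the lexicographically smallest
    canonical SMILES, keeping the choice deterministic.
    """
    if isinstance(mol_or_smiles, str):
        mol = Chem.MolFromSmiles(mol_or_smiles)
        if mol is None:
            raise ValueError(f"unparsable SMILES {mol_or_smiles!r}")
    else:
        mol = mol_or_smiles
    frags = Chem.MolToSmiles(mol).split(".")
    scored = sorted(
        (Chem.MolFromSmiles(f).GetNumHeavyAtoms(), f) for f in frags
    )
    return scored[-1][1] if scored else ""


def dedup_key(smiles: str) -> str:
    """Structure-identity key: full InChIKey of the largest fragment."""
    frag = largest_fragment(smiles)
    mol = Chem.MolFromSmiles(frag)
    key = Chem.MolToInchiKey(mol)
    # extremely exotic structures can defeat the InChI algorithm; fall back
    # to canonical SMILES so the product is still deduplicable
    return key if key else f"SMILES:{frag}"


class _TemplateIndex:
    """Compiled template/substructure tables keyed by template_id."""

    def __init__(self, templates: pd.DataFrame, substructures: pd.DataFrame):
        self.templates = templates.sort_values("template_id").reset_index(drop=True)
        self.substructures = substructures.sort_values(
            ["template_id", "substructure_smarts"]
        ).reset_index(drop=True)
        self._rxn_cache: dict[str, AllChem.ChemicalReaction] = {}
        self._patt_cache: dict[str, Chem.Mol] = {}
        self._by_id = {
            row.template_id: row for row in self.templates.itertuples()
        }

    def reaction(self, template_id: str) -> AllChem.ChemicalReaction:
        if template_id not in self._rxn_cache:
            rxn = AllChem.ReactionFromSmarts(self._by_id[template_id].smarts)
            rxn.Initialize()
            self._rxn_cache[template_id] = rxn
        return self._rxn_cache[template_id]

    def pattern(self, smarts: str) -> Chem.Mol:
        if smarts not in self._patt_cache:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"substructure SMARTS does not compile: {smarts}")
            self._patt_cache[smarts] = patt
        return self._patt_cache[smarts]

    def row(self, template_id: str):
        return self._by_id[template_id]


def screen_templates(
    query: QueryCompound | str,
    substructures: pd.DataFrame,
    index: _TemplateIndex | None = None,
) -> list[tuple[str, str]]:
    """Templates whose reactive-site substructure matches the query.

    Returns deduplicated ``(rxn_id, template_id)`` pairs sorted by
    template_id, so the order is deterministic.
    """
    if isinstance(query, str):
        query = QueryCompound("query", query)
    patt_of = index.pattern if index else (
        lambda s: Chem.MolFromSmarts(s)
    )
    hits: set[tuple[str, str]] = set()
    for row in substructures.itertuples():
        patt = patt_of(row.substructure_smarts)
        if query.mol.HasSubstructMatch(patt):
            hits.add((row.rxn_id, row.template_id))
    return sorted(hits, key=lambda x: (x[1], x[0]))


def apply_template(
    query: QueryCompound | str,
    template_row,
    index: _TemplateIndex | None = None,
    multi_reactant_policy: str = "fill",
) -> tuple[set[str], dict]:
    """Apply one template to a query; principal product per embedding.

    For multi-reactant templates the query is substituted into every reactant
    role it matches; remaining roles are filled with the source reaction's
    own co-reactants (policy ``"fill"``) or the template is skipped (policy
    ``"single_only"``). Unsanitizable embeddings are dropped and counted.
    """
    if isinstance(query, str):
        query = QueryCompound("query", query)
    if multi_reactant_policy not in ("fill", "single_only"):
        raise ValueError(f"unknown policy {multi_reactant_policy!r}")
    rxn = (
        index.reaction(template_row.template_id)
        if index
        else AllChem.ReactionFromSmarts(template_row.smarts)
    )
    n_roles = rxn.GetNumReactantTemplates()
    counts = {"n_embeddings": 0, "n_unsanitizable": 0}
    if n_roles > 1 and multi_reactant_policy == "single_only":
        return set(), counts
    sources = str(template_row.reactant_smiles).split(_LIST_SEP)
    products: set[str] = set()
    for role in range(n_roles):
        role_patt = rxn.GetReactantTemplate(role)
        if not query.mol.HasSubstructMatch(role_patt):
            continue
        reactants = []
        for k in range(n_roles):
            if k == role:
                reactants.append(query.mol)
            else:
                reactants.append(Chem.MolFromSmiles(sources[k]))
        try:
            tuples = rxn.RunReactants(tuple(reactants))
        except Exception as exc:  # engine-level failure: log, empty result
            logger.warning(
                "template %s failed on %s: %s",
                template_row.template_id,
                query.query_id,
                exc,
            )
            return set(), counts
        for tup in tuples:
            counts["n_embeddings"] += 1
            frags: list[str] = []
            ok = True
            for prod in tup:
                try:
                    Chem.SanitizeMol(prod)
                except Exception:
                    ok = False
                    break
                frags.extend(Chem.MolToSmiles(prod).split("."))
            if not ok:
                counts["n_unsanitizable"] += 1
                continue
            products.add(largest_fragment(".".join(frags)))
    return products, counts


def transform(
    queries: list[QueryCompound],
    templates: pd.DataFrame,
    substructures: pd.DataFrame,
    multi_reactant_policy: str = "fill",
    dedup_scope: str = "per_query",
    exclude_parent: bool = True,
    use_screen: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Enumerate transformation products for a query list.

    Products are deduplicated by ``dedup_key`` within each query (scope
    ``"per_query"``) or across the whole run (``"global"``); the summary
    reports both unique-product notions. ``use_screen=False`` applies every
    template exhaustively (the brute-force oracle path).
    """
    if dedup_scope not in ("per_query", "global"):
        raise ValueError(f"unknown dedup scope {dedup_scope!r}")
    index = _TemplateIndex(templates, substructures)
    rows: list[dict] = []
    per_query_counts: dict[str, int] = {}
    n_failed = 0
    global_keys: set[str] = set()
    for query in queries:
        try:
            parent_key = dedup_key(query.smiles)
            if use_screen:
                hits = screen_templates(query, index.substructures, index)
            else:
                hits = sorted(
                    {
                        (row.rxn_id, row.template_id)
                        for row in index.templates.itertuples()
                    },
                    key=lambda x: (x[1], x[0]),
                )
            seen: set[str] = set()
            for _rxn_id, template_id in hits:
                trow = index.row(template_id)
                prods, _ = apply_template(
                    query, trow, index, multi_reactant_policy
                )
                for smi in sorted(prods):
                    key = dedup_key(smi)
                    if exclude_parent and key == parent_key:
                        continue
                    if key in seen:
                        continue
                    if dedup_scope == "global" and key in global_keys:
                        continue
                    seen.add(key)
                    global_keys.add(key)
                    rows.append(
                        {
                            "query_id": query.query_id,
                            "query_smiles": query.smiles,
                            "product_smiles": smi,
                            "dedup_key": key,
                            "rxn_id": trow.rxn_id,
                            "template_id": template_id,
                            "known_cid": "",
                        }
                    )
            per_query_counts[query.query_id] = len(seen)
        except Exception as exc:
            n_failed += 1
            logger.warning("query %s failed: %s", query.query_id, exc)
            per_query_counts[query.query_id] = 0
    frame = pd.DataFrame(rows, columns=PRODUCT_COLUMNS)
    counts = pd.Series(per_query_counts, dtype=int)
    summary = {
        "n_queries": len(queries),
        "n_queries_with_products": int((counts > 0).sum()),
        "n_queries_failed": n_failed,
        "n_product_rows": len(frame),
        "n_unique_products_global": frame["dedup_key"].nunique(),
        "median_products_per_query": (
            float(counts.median()) if len(counts) else 0.0
        ),
        "per_query_counts": per_query_counts,
    }
    return frame, summary


def load_snapshot(path: str | Path) -> pd.DataFrame:
    """Load a known-compound snapshot (CID ↔ SMILES/InChIKey table).

    Accepts CSV/TSV with a CID column and at least one of SMILES or
    INCHIKEY; missing InChIKeys are computed from SMILES.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    snap = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    cols = {c.upper(): c for c in snap.columns}
    if "CID" not in cols or ("SMILES" not in cols and "INCHIKEY" not in cols):
        raise KeyError(f"{path}: snapshot needs CID and SMILES or INCHIKEY")
    keys = []
    for _, row in snap.iterrows():
        key = row[cols["INCHIKEY"]] if "INCHIKEY" in cols else ""
        if not key and "SMILES" in cols and row[cols["SMILES"]]:
            mol = Chem.MolFromSmiles(row[cols["SMILES"]])
            key = Chem.MolToInchiKey(mol) if mol else ""
        keys.append(key)
    return pd.DataFrame(
        {"cid": snap[cols["CID"]].astype(str), "inchikey": keys}
    )


def annotate_known(
    products: pd.DataFrame, snapshot: pd.DataFrame | str | Path | None
) -> tuple[pd.DataFrame, dict]:
    """Fill ``known_cid`` by exact structure identity against the snapshot.

    A missing snapshot skips annotation with a warning rather than failing.
    """
    products = products.copy()
    if snapshot is None:
        logger.warning("no known-compound snapshot: annotation skipped")
        return products, {"n_products": len(products), "n_known": 0,
                          "match_rate": 0.0, "skipped": True}
    if isinstance(snapshot, (str, Path)):
        if not Path(snapshot).exists():
            logger.warning(
                "snapshot %s missing: annotation skipped", snapshot
            )
            return products, {"n_products": len(products), "n_known": 0,
                              "match_rate": 0.0, "skipped": True}
        snapshot = load_snapshot(snapshot)
    lookup = (
        snapshot[snapshot["inchikey"] != ""]
        .drop_duplicates("inchikey")
        .set_index("inchikey")["cid"]
    )
    # dedup_key is the InChIKey of the largest fragment, so exact identity
    # match is a direct index lookup
    products["known_cid"] = (
        products["dedup_key"].map(lookup).fillna("").astype(str)
    )
    n_known = int((products["known_cid"] != "").sum())
    rate = n_known / len(products) if len(products) else 0.0
    return products, {
        "n_products": len(products),
        "n_known": n_known,
        "match_rate": rate,
        "skipped": False,
    }
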