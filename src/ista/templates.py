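"""Transformation-template and reactive-substructure extraction.

From each sanitized atom-mapped reaction, atoms whose local properties
(atomic number, hydrogen count, formal charge, degree, radical electrons,
aromaticity, or neighbor identity) differ between their reactant and product
instances are flagged as changed; the changed set is expanded by radius 1
(direct neighbors) and completed with any expansion-tier functional group
touching it. The expanded reactant context and its product-side image are
serialized as a forward reaction-SMARTS template, validated by round-trip
application to the source reactants. Per-reactant reactive-site SMARTS are
emitted alongside as the screening database.

Template atom queries are strict on changed atoms (element, aromaticity,
H count, charge) and looser on context atoms (element, aromaticity, charge),
so templates generalize to decorated analogues while preserving the reactive
environment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .annotation import FunctionalGroupLibrary, default_fg_library, fg_atom_sets
from .center import MappedReaction, SanitizationError, sanitize_mapped_reaction
from .io import ReactionRecord, filter_reactions

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateError",
    "ReactionTemplate",
    "SubstructureRecord",
    "changed_atoms",
    "expand_atoms",
    "extract_template",
    "build_template_db",
    "TEMPLATE_COLUMNS",
    "SUBSTRUCTURE_COLUMNS",
]


class TemplateError(ValueError):
    """Template extraction failed for one reaction (logged, not fatal)."""


@dataclass
class ReactionTemplate:
    """A forward transformation pattern with provenance.

    ``smarts`` is a reaction SMARTS (reactant pattern(s) ``>>`` product
    pattern(s)) applied parent→product; ``reactant_smiles`` holds the source
    reactant of each pattern role (used to fill co-reactant roles when a
    query occupies only one role).
    """

    template_id: str
    rxn_id: str
    smarts: str
    n_reactant_patterns: int
    reactant_smiles: list[str] = field(default_factory=list)
    product_smiles: list[str] = field(default_factory=list)


@dataclass
class SubstructureRecord:
    """Reactive-site SMARTS for one reactant, with provenance and atom sets."""

    substructure_smarts: str
    parent_smiles: str
    rxn_id: str
    template_id: str
    changed_atoms: list[int]
    expanded_atoms: list[int]

    def __post_init__(self) -> None:
        if not set(self.changed_atoms) <= set(self.expanded_atoms):
            raise ValueError("changed_atoms must be a subset of expanded_atoms")


_COMPARED_PROPS = (
    "atomic number",
    "hydrogens",
    "formal charge",
    "degree",
    "radicals",
    "aromaticity",
    "neighbors",
)


def _atom_signature(atom: Chem.Atom) -> tuple:
    """The compared per-atom properties.

    Neighbor identity is the multiset of (neighbor identity, bond order)
    pairs, where a mapped neighbor is identified by its atom-map number (the
    tracked atom itself, so an O→O substitution still registers) and an
    unmapped one by its element.
    """

    def nbr_id(nbr: Chem.Atom) -> int:
        mapnum = nbr.GetAtomMapNum()
        return mapnum if mapnum > 0 else -nbr.GetAtomicNum()

    neighbors = tuple(
        sorted(
            (nbr_id(b.GetOtherAtom(atom)), b.GetBondTypeAsDouble())
            for b in atom.GetBonds()
        )
    )
    return (
        atom.GetAtomicNum(),
        atom.GetTotalNumHs(),
        atom.GetFormalCharge(),
        atom.GetDegree(),
        atom.GetNumRadicalElectrons(),
        atom.GetIsAromatic(),
        neighbors,
    )


def changed_atoms(reaction: MappedReaction) -> dict[int, set[int]]:
    """Per-reactant sets of changed atom indices.

    An atom is changed iff any compared property differs between its reactant
    and product instances, or it has no product counterpart.
    """
    out: dict[int, set[int]] = {}
    for mapnum, (mi, ai) in reaction.reactant_index.items():
        r_atom = reaction.reactant_mols[mi].GetAtomWithIdx(ai)
        if mapnum not in reaction.product_index:
            out.setdefault(mi, set()).add(ai)
            continue
        p_atom = reaction.product_atom(mapnum)
        if _atom_signature(r_atom) != _atom_signature(p_atom):
            out.setdefault(mi, set()).add(ai)
    return out


def expand_atoms(
    mol: Chem.Mol,
    changed: set[int],
    library: FunctionalGroupLibrary | None = None,
) -> set[int]:
    """Radius-1 expansion plus functional-group completion.

    The transformed set is the changed atoms plus their direct neighbors;
    every expansion-tier FG match sharing at least one atom with that set is
    then included whole.
    """
    library = library or default_fg_library()
    if not changed <= {a.GetIdx() for a in mol.GetAtoms()}:
        raise ValueError("changed atoms outside molecule")
    base = set(changed)
    for idx in changed:
        for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
            base.add(nb.GetIdx())
    expanded = set(base)
    for _name, atoms in fg_atom_sets(mol, library, tier="expansion"):
        if atoms & base:
            expanded |= atoms
    return expanded


_BOND_SYMBOL = {1.0: "-", 1.5: ":", 2.0: "=", 3.0: "#"}


def _charge_query(charge: int) -> str:
    if charge == 0:
        return "+0"
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return sign if mag == 1 else f"{sign}{mag}"


def _reactant_atom_query(atom: Chem.Atom, strict: bool) -> str:
    parts = [f"#{atom.GetAtomicNum()}", "a" if atom.GetIsAromatic() else "A"]
    if strict:
        parts.append(f"H{atom.GetTotalNumHs()}")
    parts.append(_charge_query(atom.GetFormalCharge()))
    return "[" + ";".join(parts) + f":{atom.GetAtomMapNum()}]"


def _product_atom_query(atom: Chem.Atom, strict: bool) -> str:
    """Product-side atom query.

    Changed atoms (and created, unmapped atoms) pin element, aromaticity,
    H count and charge so the engine rebuilds their exact product state;
    unchanged context atoms stay loose (element + aromaticity only) so their
    hydrogens and charge are inherited from the matched query atom.
    """
    parts = [f"#{atom.GetAtomicNum()}", "a" if atom.GetIsAromatic() else "A"]
    if strict:
        parts += [f"H{atom.GetTotalNumHs()}", _charge_query(atom.GetFormalCharge())]
    mapnum = atom.GetAtomMapNum()
    tag = f":{mapnum}" if mapnum else ""
    return "[" + ";".join(parts) + tag + "]"


def _fragment_smarts(
    mol: Chem.Mol, atoms: list[int], symbols: dict[int, str]
) -> str:
    atom_symbols = [
        symbols.get(a.GetIdx(), "*") for a in mol.GetAtoms()
    ]
    bond_symbols = [
        _BOND_SYMBOL[b.GetBondTypeAsDouble()] for b in mol.GetBonds()
    ]
    smarts = Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=atoms,
        atomSymbols=atom_symbols,
        bondSymbols=bond_symbols,
        canonical=True,
        allBondsExplicit=True,
    )
    # a disconnected pattern within one molecule must stay one component
    return f"({smarts})" if "." in smarts else smarts


def _strip_maps(mol: Chem.Mol) -> Chem.Mol:
    clean = Chem.Mol(mol)
    for a in clean.GetAtoms():
        a.SetAtomMapNum(0)
    return clean


def canonical_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(_strip_maps(mol))


def _renumber_template(smarts: str) -> str:
    """Renumber atom maps to 1..k by first appearance so identical patterns
    from different reactions serialize identically."""
    mapping: dict[str, str] = {}
    counter = [0]

    def repl(m: re.Match) -> str:
        old = m.group(1)
        if old not in mapping:
            counter[0] += 1
            mapping[old] = str(counter[0])
        return f":{mapping[old]}]"

    return re.sub(r":(\d+)\]", repl, smarts)


def extract_template(
    reaction: MappedReaction,
    library: FunctionalGroupLibrary | None = None,
    template_id: str | None = None,
    validate: bool = True,
) -> tuple[ReactionTemplate, list[SubstructureRecord]]:
    """Extract a forward template and per-reactant substructure records.

    Raises :class:`TemplateError` on an empty changed set (identity reaction),
    failed SMARTS assembly, or a failed round-trip (applying the template to
    its own reactants must reproduce the covered source products).
    """
    library = library or default_fg_library()
    template_id = template_id or f"T_{reaction.rxn_id}"
    changed = changed_atoms(reaction)
    if not changed:
        raise TemplateError(
            f"reaction {reaction.rxn_id}: no changed atoms (identity reaction)"
        )

    roles: list[tuple[int, str, str]] = []  # (mol index, pattern, source smiles)
    substructures: list[SubstructureRecord] = []
    expanded_maps: set[int] = set()
    changed_maps: set[int] = set()
    for mi in sorted(changed):
        mol = reaction.reactant_mols[mi]
        ch = changed[mi]
        for idx in ch:
            mapnum = mol.GetAtomWithIdx(idx).GetAtomMapNum()
            if mapnum:
                changed_maps.add(mapnum)
        exp = expand_atoms(mol, ch, library)
        symbols = {
            idx: _reactant_atom_query(mol.GetAtomWithIdx(idx), strict=idx in ch)
            for idx in exp
        }
        pattern = _fragment_smarts(mol, sorted(exp), symbols)
        roles.append((mi, pattern, canonical_smiles(mol)))
        substructures.append(
            SubstructureRecord(
                substructure_smarts=pattern,
                parent_smiles=canonical_smiles(mol),
                rxn_id=reaction.rxn_id,
                template_id=template_id,
                changed_atoms=sorted(ch),
                expanded_atoms=sorted(exp),
            )
        )
        for idx in exp:
            mapnum = mol.GetAtomWithIdx(idx).GetAtomMapNum()
            if mapnum:
                expanded_maps.add(mapnum)

    product_patterns: list[str] = []
    covered_products: list[str] = []
    for mol in reaction.product_mols:
        include = {
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomMapNum() in expanded_maps
        }
        if not include:
            continue
        # pull in unmapped atoms created next to the transformed context
        frontier = set(include)
        while frontier:
            new = set()
            for idx in frontier:
                for nb in mol.GetAtomWithIdx(idx).GetNeighbors():
                    if nb.GetAtomMapNum() == 0 and nb.GetIdx() not in include:
                        new.add(nb.GetIdx())
            include |= new
            frontier = new
        symbols = {
            idx: _product_atom_query(
                mol.GetAtomWithIdx(idx),
                strict=(
                    mol.GetAtomWithIdx(idx).GetAtomMapNum() in changed_maps
                    or mol.GetAtomWithIdx(idx).GetAtomMapNum() == 0
                ),
            )
            for idx in include
        }
        product_patterns.append(_fragment_smarts(mol, sorted(include), symbols))
        covered_products.append(canonical_smiles(mol))

    if not product_patterns:
        raise TemplateError(
            f"reaction {reaction.rxn_id}: no product-side image of the "
            "transformed atoms"
        )

    smarts = _renumber_template(
        ".".join(p for _, p, _ in roles) + ">>" + ".".join(product_patterns)
    )
    template = ReactionTemplate(
        template_id=template_id,
        rxn_id=reaction.rxn_id,
        smarts=smarts,
        n_reactant_patterns=len(roles),
        reactant_smiles=[smi for _, _, smi in roles],
        product_smiles=covered_products,
    )
    if validate:
        _validate_round_trip(template, reaction, roles)
    return template, substructures


def _validate_round_trip(
    template: ReactionTemplate,
    reaction: MappedReaction,
    roles: list[tuple[int, str, str]],
) -> None:
    rxn = AllChem.ReactionFromSmarts(template.smarts)
    if rxn is None or rxn.Validate()[1] != 0:
        raise TemplateError(
            f"reaction {reaction.rxn_id}: template SMARTS does not compile: "
            f"{template.smarts}"
        )
    reactants = tuple(
        _strip_maps(reaction.reactant_mols[mi]) for mi, _, _ in roles
    )
    want = set(template.product_smiles)
    for tup in rxn.RunReactants(reactants):
        got = set()
        ok = True
        for prod in tup:
            try:
                Chem.SanitizeMol(prod)
            except Exception:
                ok = False
                break
            got.add(Chem.MolToSmiles(prod))
        if ok and want <= got:
            return
    raise TemplateError(
        f"reaction {reaction.rxn_id}: round-trip failed for template "
        f"{template.smarts}"
    )


TEMPLATE_COLUMNS = [
    "template_id",
    "rxn_id",
    "smarts",
    "n_reactant_patterns",
    "reactant_smiles",
    "product_smiles",
]
SUBSTRUCTURE_COLUMNS = [
    "substructure_smarts",
    "parent_smiles",
    "rxn_id",
    "template_id",
    "changed_atoms",
    "expanded_atoms",
]

_LIST_SEP = "|"


def templates_to_frame(templates: list[ReactionTemplate]) -> pd.DataFrame:
    rows = [
        {
            "template_id": t.template_id,
            "rxn_id": t.rxn_id,
            "smarts": t.smarts,
            "n_reactant_patterns": t.n_reactant_patterns,
            "reactant_smiles": _LIST_SEP.join(t.reactant_smiles),
            "product_smiles": _LIST_SEP.join(t.product_smiles),
        }
        for t in templates
    ]
    return pd.DataFrame(rows, columns=TEMPLATE_COLUMNS)


def substructures_to_frame(records: list[SubstructureRecord]) -> pd.DataFrame:
    rows = [
        {
            "substructure_smarts": s.substructure_smarts,
            "parent_smiles": s.parent_smiles,
            "rxn_id": s.rxn_id,
            "template_id": s.template_id,
            "changed_atoms": _LIST_SEP.join(map(str, s.changed_atoms)),
            "expanded_atoms": _LIST_SEP.join(map(str, s.expanded_atoms)),
        }
        for s in records
    ]
    return pd.DataFrame(rows, columns=SUBSTRUCTURE_COLUMNS)


def build_template_db(
    records: list[ReactionRecord],
    library: FunctionalGroupLibrary | None = None,
    apply_filter: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Extract templates and substructures for a reaction record set.

    CID-redundant and CID-incomplete records are filtered first (as in the
    data-preparation stage); per-record extraction failures are logged and
    counted, never fatal. Output row content is independent of input order up
    to row permutation.
    """
    library = library or default_fg_library()
    skip_report = {
        "n_input": len(records),
        "n_filtered_out": 0,
        "n_unmapped": 0,
        "n_sanitization_failed": 0,
        "n_template_failed": 0,
        "n_templates": 0,
    }
    if apply_filter:
        records, filt = filter_reactions(records)
        skip_report["n_filtered_out"] = filt.n_dropped
    templates: list[ReactionTemplate] = []
    substructures: list[SubstructureRecord] = []
    for rec in records:
        if not rec.mapped_reaction_smiles:
            skip_report["n_unmapped"] += 1
            logger.warning("reaction %s: no mapped reaction SMILES", rec.rxn_id)
            continue
        try:
            mapped = sanitize_mapped_reaction(
                rec.mapped_reaction_smiles, rec.rxn_id
            )
        except SanitizationError as exc:
            skip_report["n_sanitization_failed"] += 1
            logger.warning("%s", exc)
            continue
        try:
            template, subs = extract_template(mapped, library)
        except TemplateError as exc:
            skip_report["n_template_failed"] += 1
            logger.warning("%s", exc)
            continue
        templates.append(template)
        substructures.extend(subs)
    skip_report["n_templates"] = len(templates)
    t_frame = templates_to_frame(
        sorted(templates, key=lambda t: t.template_id)
    )
    s_frame = substructures_to_frame(
        sorted(substructures, key=lambda s: (s.template_id, s.substructure_smarts))
    )
    return t_frame, s_frame, skip_report
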