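"""Reaction classification and annotation.

Assigns each sanitized mapped reaction one of ten classes through an ordered
rule cascade (protection, deprotection, oxidation, reduction, aromatic
heterocycle formation, acylation, C-C coupling, heteroatom alkylation and
arylation, functional group addition, functional group interconversion, with
"miscellaneous" as the fall-through), and annotates functional groups,
N/O/S participation in the reaction center, ring involvement, Murcko
scaffolds, and spectator molecules. Rule order is configuration
(``data/class_rules.yaml``); the FG libraries are editable TSV
(``data/functional_groups.tsv``, detection tier n=107, expansion tier n=30).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .center import MappedReaction, TMatrix, t_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CLASS_LABELS",
    "FunctionalGroupLibrary",
    "ReactionAnnotation",
    "load_fg_library",
    "load_class_rules",
    "detect_functional_groups",
    "classify_reaction",
    "find_spectators",
    "annotate_reaction",
]

#: The fixed class vocabulary (ten classes + fall-through).
CLASS_LABELS = (
    "acylation",
    "aromatic heterocycle formation",
    "C-C coupling",
    "heteroatom alkylation and arylation",
    "functional group addition",
    "functional group interconversion",
    "protection",
    "deprotection",
    "oxidation",
    "reduction",
    "miscellaneous",
)

_NOS = {7, 8, 16}


@dataclass
class FunctionalGroupLibrary:
    """Compiled two-tier SMARTS library (detection n=107, expansion n=30)."""

    detection: list[tuple[str, Chem.Mol]] = field(default_factory=list)
    expansion: list[tuple[str, Chem.Mol]] = field(default_factory=list)

    def tier(self, name: str) -> list[tuple[str, Chem.Mol]]:
        if name not in ("detection", "expansion"):
            raise KeyError(name)
        return getattr(self, name)


@dataclass
class ReactionAnnotation:
    rxn_id: str
    class_label: str
    fg_reactants: Counter
    fg_products: Counter
    nos_in_center: bool
    ring_in_center: bool
    ring_changed: bool
    has_scaffold: bool
    n_reactants: int
    n_products: int
    spectators: list[tuple[str, int]]  # (side, molecule index)

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")


def load_fg_library(path: str | Path | None = None) -> FunctionalGroupLibrary:
    """Load the TSV functional-group library (columns name/smarts/tier)."""
    if path is None:
        ref = resources.files("ista.data") / "functional_groups.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lib = FunctionalGroupLibrary()
    seen: dict[str, set[str]] = {"detection": set(), "expansion": set()}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        name, smarts, tier = row["name"], row["smarts"], row["tier"]
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"FG {name!r}: SMARTS does not compile: {smarts}")
        if name in seen[tier]:
            raise ValueError(f"duplicate FG name {name!r} in tier {tier}")
        seen[tier].add(name)
        lib.tier(tier).append((name, patt))
    return lib


_DEFAULT_LIB: FunctionalGroupLibrary | None = None


def default_fg_library() -> FunctionalGroupLibrary:
    global _DEFAULT_LIB
    if _DEFAULT_LIB is None:
        _DEFAULT_LIB = load_fg_library()
    return _DEFAULT_LIB


def load_class_rules(path: str | Path | None = None) -> dict:
    """Load the ordered rule cascade and protecting-group patterns."""
    if path is None:
        text = (resources.files("ista.data") / "class_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    pgs = []
    for name, smarts in cfg.get("protecting_groups", {}).items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"protecting group {name!r}: bad SMARTS")
        pgs.append((name, patt))
    return {"rules": list(cfg["rules"]), "protecting_groups": pgs}


_DEFAULT_RULES: dict | None = None


def default_class_rules() -> dict:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_class_rules()
    return _DEFAULT_RULES


def detect_functional_groups(
    mol: Chem.Mol, library: FunctionalGroupLibrary | None = None,
    tier: str = "detection",
) -> Counter:
    """Multiset of FG names, one count per distinct substructure match.

    Symmetry-equivalent matches covering the same atom set are collapsed.
    """
    library = library or default_fg_library()
    counts: Counter = Counter()
    for name, patt in library.tier(tier):
        matches = {
            frozenset(m) for m in mol.GetSubstructMatches(patt, uniquify=True)
        }
        if matches:
            counts[name] = len(matches)
    return counts


def fg_atom_sets(
    mol: Chem.Mol, library: FunctionalGroupLibrary | None = None,
    tier: str = "expansion",
) -> list[tuple[str, frozenset[int]]]:
    """All (name, atom-index set) FG matches of one tier, for FG completion."""
    library = library or default_fg_library()
    out = []
    for name, patt in library.tier(tier):
        for m in mol.GetSubstructMatches(patt, uniquify=True):
            out.append((name, frozenset(m)))
    return out


# ---------------------------------------------------------------------------
# classification cascade
# ---------------------------------------------------------------------------


def _changed_bonds(t: TMatrix) -> list[tuple[int, int, float]]:
    """Off-diagonal R-matrix changes as (map_i, map_j, delta) with i<j."""
    out = []
    order = t.atom_order
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            d = t.r_values[i, j]
            if d != 0:
                out.append((order[i], order[j], float(d)))
    return out


def _atom_on_side(rxn: MappedReaction, mapnum: int, side: str) -> Chem.Atom | None:
    index = rxn.reactant_index if side == "r" else rxn.product_index
    if mapnum not in index:
        return None
    return rxn.reactant_atom(mapnum) if side == "r" else rxn.product_atom(mapnum)


def _oxidation_delta(rxn: MappedReaction, center: list[int]) -> float:
    """Oxidation-state proxy change summed over center carbon atoms.

    Per carbon: (total bond order to N, O, S, halogens) minus (H count);
    product minus reactant. Positive totals indicate oxidation.
    """
    hetero = {7, 8, 16, 9, 17, 35, 53}

    def score(atom: Chem.Atom | None) -> float:
        if atom is None:
            return 0.0
        s = -float(atom.GetTotalNumHs())
        for b in atom.GetBonds():
            other = b.GetOtherAtom(atom)
            if other.GetAtomicNum() in hetero:
                s += b.GetBondTypeAsDouble()
        return s

    total = 0.0
    for m in center:
        ra = _atom_on_side(rxn, m, "r")
        pa = _atom_on_side(rxn, m, "p")
        if (ra or pa).GetAtomicNum() != 6:
            continue
        total += score(pa) - score(ra)
    return total


def _pg_match_count(mols: list[Chem.Mol], pgs) -> int:
    return sum(len(mol.GetSubstructMatches(p)) for mol in mols for _, p in pgs)


def _is_carbonyl_carbon(atom: Chem.Atom | None) -> bool:
    if atom is None or atom.GetAtomicNum() != 6:
        return False
    return any(
        b.GetBondTypeAsDouble() == 2.0 and b.GetOtherAtom(atom).GetAtomicNum() == 8
        for b in atom.GetBonds()
    )


def _aromatic_hetero_ring_count(mols: list[Chem.Mol]) -> int:
    n = 0
    for mol in mols:
        for ring in mol.GetRingInfo().AtomRings():
            atoms = [mol.GetAtomWithIdx(i) for i in ring]
            if all(a.GetIsAromatic() for a in atoms) and any(
                a.GetAtomicNum() in _NOS for a in atoms
            ):
                n += 1
    return n


def classify_reaction(
    t: TMatrix,
    reaction: MappedReaction,
    fg_reactants: Counter | None = None,
    fg_products: Counter | None = None,
    rules: dict | None = None,
) -> str:
    """Assign exactly one of the ten class labels via the ordered cascade.

    The cascade order comes from ``class_rules.yaml``; unmatched reactions
    (including identity reactions with an empty center) are "miscellaneous".
    """
    rules = rules or default_class_rules()
    if fg_reactants is None:
        fg_reactants = sum(
            (detect_functional_groups(m) for m in reaction.reactant_mols), Counter()
        )
    if fg_products is None:
        fg_products = sum(
            (detect_functional_groups(m) for m in reaction.product_mols), Counter()
        )

    center = t.center_atoms
    if not center:
        return "miscellaneous"
    bonds = _changed_bonds(t)
    formed = [(i, j) for i, j, d in bonds if d > 0]
    broken = [(i, j) for i, j, d in bonds if d < 0]

    def elem(m: int) -> int:
        a = _atom_on_side(reaction, m, "r") or _atom_on_side(reaction, m, "p")
        return a.GetAtomicNum()

    pgs = rules["protecting_groups"]

    def pred_protection() -> bool:
        return _pg_match_count(reaction.product_mols, pgs) > _pg_match_count(
            reaction.reactant_mols, pgs
        )

    def pred_deprotection() -> bool:
        return _pg_match_count(reaction.product_mols, pgs) < _pg_match_count(
            reaction.reactant_mols, pgs
        )

    def pred_oxidation() -> bool:
        return _oxidation_delta(reaction, center) > 0

    def pred_reduction() -> bool:
        return _oxidation_delta(reaction, center) < 0

    def pred_het_ring_formation() -> bool:
        return _aromatic_hetero_ring_count(
            reaction.product_mols
        ) > _aromatic_hetero_ring_count(reaction.reactant_mols)

    def pred_acylation() -> bool:
        # a new bond from a product-side carbonyl carbon to N/S, or to an O
        # that carries another carbon (alkoxy); hydration/hydrolysis O (water
        # oxygen with no other heavy neighbour) does not count
        for i, j in formed:
            for c_m, x_m in ((i, j), (j, i)):
                pa = _atom_on_side(reaction, c_m, "p")
                if not _is_carbonyl_carbon(pa):
                    continue
                x_elem = elem(x_m)
                if x_elem in (7, 16):
                    return True
                if x_elem == 8:
                    xa = _atom_on_side(reaction, x_m, "r")
                    if xa is not None and any(
                        nb.GetAtomicNum() == 6 for nb in xa.GetNeighbors()
                    ):
                        return True
        return False

    def pred_cc_coupling() -> bool:
        return any(
            elem(i) == 6 and elem(j) == 6 and (i, j) not in broken for i, j in formed
        )

    def pred_het_alkylation() -> bool:
        for i, j in formed:
            for c_m, x_m in ((i, j), (j, i)):
                if elem(x_m) not in _NOS or elem(c_m) != 6:
                    continue
                if not _is_carbonyl_carbon(_atom_on_side(reaction, c_m, "p")):
                    return True
        return False

    def pred_fg_addition() -> bool:
        return bool(formed) and not broken and fg_products != fg_reactants

    def pred_fg_interconversion() -> bool:
        return fg_products != fg_reactants

    predicates = {
        "protection": pred_protection,
        "deprotection": pred_deprotection,
        "oxidation": pred_oxidation,
        "reduction": pred_reduction,
        "aromatic heterocycle formation": pred_het_ring_formation,
        "acylation": pred_acylation,
        "C-C coupling": pred_cc_coupling,
        "heteroatom alkylation and arylation": pred_het_alkylation,
        "functional group addition": pred_fg_addition,
        "functional group interconversion": pred_fg_interconversion,
    }
    for name in rules["rules"]:
        if predicates[name]():
            return name
    return "miscellaneous"


def find_spectators(
    reaction: MappedReaction, t: TMatrix
) -> list[tuple[str, int]]:
    """Molecules untouched by the reaction (reagents, solvents, catalysts).

    A molecule is a spectator when none of its atoms is a center atom and its
    canonical (map-stripped) structure occurs on both sides.
    """
    center = set(t.center_atoms)

    def canon(mol: Chem.Mol) -> str:
        clean = Chem.Mol(mol)
        for a in clean.GetAtoms():
            a.SetAtomMapNum(0)
        return Chem.MolToSmiles(clean)

    r_canon = [canon(m) for m in reaction.reactant_mols]
    p_canon = [canon(m) for m in reaction.product_mols]

    def untouched(mol: Chem.Mol) -> bool:
        return all(
            a.GetAtomMapNum() == 0 or a.GetAtomMapNum() not in center
            for a in mol.GetAtoms()
        )

    out: list[tuple[str, int]] = []
    for side, mols, own, other in (
        ("reactant", reaction.reactant_mols, r_canon, p_canon),
        ("product", reaction.product_mols, p_canon, r_canon),
    ):
        for mi, mol in enumerate(mols):
            if untouched(mol) and own[mi] in other:
                out.append((side, mi))
    return out


def _ring_changed(reaction: MappedReaction) -> bool:
    """True when any mapped atom changes ring membership between sides."""
    for m in set(reaction.reactant_index) & set(reaction.product_index):
        if reaction.reactant_atom(m).IsInRing() != reaction.product_atom(m).IsInRing():
            return True
    return False


def _has_scaffold(mols: list[Chem.Mol]) -> bool:
    for mol in mols:
        clean = Chem.Mol(mol)
        for a in clean.GetAtoms():
            a.SetAtomMapNum(0)
        if MurckoScaffold.MurckoScaffoldSmiles(mol=clean, includeChirality=False):
            return True
    return False


def annotate_reaction(
    reaction: MappedReaction,
    library: FunctionalGroupLibrary | None = None,
    rules: dict | None = None,
    t: TMatrix | None = None,
) -> ReactionAnnotation:
    """Full per-reaction annotation (class, FGs, center flags, spectators)."""
    library = library or default_fg_library()
    if t is None:
        t = t_matrix(reaction)
    fg_r = sum(
        (detect_functional_groups(m, library) for m in reaction.reactant_mols),
        Counter(),
    )
    fg_p = sum(
        (detect_functional_groups(m, library) for m in reaction.product_mols),
        Counter(),
    )
    label = classify_reaction(t, reaction, fg_r, fg_p, rules)
    center = t.center_atoms

    def center_elem(m: int) -> Chem.Atom:
        return (
            _atom_on_side(reaction, m, "r") or _atom_on_side(reaction, m, "p")
        )

    nos = any(center_elem(m).GetAtomicNum() in _NOS for m in center)
    ring = any(center_elem(m).IsInRing() for m in center)
    return ReactionAnnotation(
        rxn_id=reaction.rxn_id,
        class_label=label,
        fg_reactants=fg_r,
        fg_products=fg_p,
        nos_in_center=nos,
        ring_in_center=ring,
        ring_changed=_ring_changed(reaction),
        has_scaffold=_has_scaffold(reaction.reactant_mols + reaction.product_mols),
        n_reactants=len(reaction.reactant_mols),
        n_products=len(reaction.product_mols),
        spectators=find_spectators(reaction, t),
    )
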