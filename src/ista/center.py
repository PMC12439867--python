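"""Reaction-center detection via bond-electron matrices.

An atom-mapped reaction is sanitized, each side is encoded as a combined
bond-electron (BE) matrix over mapped heavy atoms — diagonal entries count
free (non-bonded) valence electrons, off-diagonal entries hold bond orders
(0 none, 1 single, 1.5 aromatic, 2 double, 3 triple) — and the R-matrix
(product BE minus reactant BE, aligned on atom-map numbers) localizes the
reaction center: atoms with any non-zero R row. Removing all-zero rows and
columns yields the T-matrix. All matrix values are multiples of 0.5 and thus
exactly representable in floating point, so zero tests are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "SanitizationError",
    "MappedReaction",
    "BEMatrix",
    "TMatrix",
    "sanitize_mapped_reaction",
    "be_matrix",
    "t_matrix",
]


class SanitizationError(ValueError):
    """A reaction component failed a sanitization check.

    Attributes name the failing side/component and the check that failed.
    """

    def __init__(self, message: str, component: str = "", check: str = ""):
        super().__init__(message)
        self.component = component
        self.check = check


@dataclass
class MappedReaction:
    """A sanitized atom-mapped reaction with per-side map indices.

    ``reactant_index``/``product_index`` map an atom-map number to
    ``(molecule index, atom index)`` on that side. Every product-side map
    number must also occur on the reactant side (atoms are tracked from
    substrates to products); map numbers are unique within a side.
    """

    rxn_id: str
    reactant_mols: list[Chem.Mol]
    product_mols: list[Chem.Mol]
    reactant_index: dict[int, tuple[int, int]] = field(default_factory=dict)
    product_index: dict[int, tuple[int, int]] = field(default_factory=dict)
    mapped_smiles: str = ""

    def reactant_atom(self, mapnum: int) -> Chem.Atom:
        mi, ai = self.reactant_index[mapnum]
        return self.reactant_mols[mi].GetAtomWithIdx(ai)

    def product_atom(self, mapnum: int) -> Chem.Atom:
        mi, ai = self.product_index[mapnum]
        return self.product_mols[mi].GetAtomWithIdx(ai)


@dataclass
class BEMatrix:
    """Combined bond-electron matrix for one reaction side."""

    atom_order: list[int]  # atom-map numbers, ascending
    values: np.ndarray  # square, symmetric

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class TMatrix:
    """R-matrix, its non-zero (center) atoms, and the reduced T-matrix."""

    atom_order: list[int]  # atom-map numbers indexing r_values
    r_values: np.ndarray
    center_atoms: list[int]  # map numbers with a non-zero R row
    t_values: np.ndarray  # r_values restricted to center_atoms
    centers: list[list[int]] = field(default_factory=list)
    # ``centers``: connected components of the non-zero off-diagonal graph of
    # R (plus isolated diagonal-only atoms); a reaction can have several.


def _index_side(
    mols: list[Chem.Mol], side: str, rxn_id: str
) -> dict[int, tuple[int, int]]:
    index: dict[int, tuple[int, int]] = {}
    for mi, mol in enumerate(mols):
        for atom in mol.GetAtoms():
            mapnum = atom.GetAtomMapNum()
            if mapnum == 0:
                continue
            if mapnum in index:
                raise SanitizationError(
                    f"reaction {rxn_id}: duplicate atom-map {mapnum} on {side} side",
                    component=side,
                    check="atom-map uniqueness",
                )
            index[mapnum] = (mi, atom.GetIdx())
    return index


def sanitize_mapped_reaction(
    mapped_reaction_smiles: str, rxn_id: str = ""
) -> MappedReaction:
    """Parse and sanitize an atom-mapped reaction SMILES.

    Each component must pass RDKit sanitization (valence, aromaticity,
    kekulization, hybridization-relevant perception, formal charges); a
    failure raises :class:`SanitizationError` naming the component and check.
    Unmapped spectator atoms are permitted but excluded from the map indices.
    """
    if mapped_reaction_smiles.count(">>") != 1:
        raise SanitizationError(
            f"reaction {rxn_id}: expected exactly one '>>'",
            check="syntax",
        )
    left, right = mapped_reaction_smiles.split(">>")
    sides: dict[str, list[Chem.Mol]] = {}
    for side, part in (("reactant", left), ("product", right)):
        mols = []
        for comp in (c for c in part.split(".") if c):
            mol = Chem.MolFromSmiles(comp, sanitize=False)
            if mol is None:
                raise SanitizationError(
                    f"reaction {rxn_id}: unparsable {side} {comp!r}",
                    component=comp,
                    check="parse",
                )
            try:
                Chem.SanitizeMol(mol)
            except Exception as exc:  # rdkit raises several exception types
                raise SanitizationError(
                    f"reaction {rxn_id}: {side} {comp!r} failed sanitization: {exc}",
                    component=comp,
                    check=type(exc).__name__,
                ) from exc
            mols.append(mol)
        if not mols:
            raise SanitizationError(
                f"reaction {rxn_id}: empty {side} side",
                check="syntax",
            )
        sides[side] = mols

    r_index = _index_side(sides["reactant"], "reactant", rxn_id)
    p_index = _index_side(sides["product"], "product", rxn_id)
    if not r_index or not p_index:
        raise SanitizationError(
            f"reaction {rxn_id}: each side needs at least one mapped atom",
            check="atom mapping",
        )
    orphaned = set(p_index) - set(r_index)
    if orphaned:
        raise SanitizationError(
            f"reaction {rxn_id}: product atom-maps {sorted(orphaned)} missing "
            "on reactant side",
            check="atom-map closure",
        )
    return MappedReaction(
        rxn_id=rxn_id,
        reactant_mols=sides["reactant"],
        product_mols=sides["product"],
        reactant_index=r_index,
        product_index=p_index,
        mapped_smiles=mapped_reaction_smiles,
    )


_PT = Chem.GetPeriodicTable()


def free_valence_electrons(atom: Chem.Atom) -> float:
    """Non-bonded valence electrons of a heavy atom.

    Dugundji–Ugi reading: outer-shell electrons of the element, minus the
    formal charge, minus one electron per unit of bond order (hydrogens count
    as single bonds; aromatic bonds as 1.5).
    """
    bond_orders = sum(
        b.GetBondTypeAsDouble() for b in atom.GetBonds()
    ) + atom.GetTotalNumHs()
    return (
        _PT.GetNOuterElecs(atom.GetAtomicNum())
        - atom.GetFormalCharge()
        - bond_orders
    )


def be_matrix(
    mols: list[Chem.Mol], atom_order: list[int] | None = None
) -> BEMatrix:
    """Combined BE matrix over the mapped heavy atoms of one reaction side.

    The matrix is block-structured by molecule (no inter-molecule bonds).
    ``atom_order`` may supply a superset of map numbers (for cross-side
    alignment); map numbers absent from this side get all-zero rows.
    """
    index: dict[int, tuple[int, int]] = {}
    for mi, mol in enumerate(mols):
        for atom in mol.GetAtoms():
            mapnum = atom.GetAtomMapNum()
            if mapnum == 0:
                continue
            if mapnum in index:
                raise SanitizationError(
                    f"duplicate atom-map {mapnum} within one side",
                    check="atom-map uniqueness",
                )
            index[mapnum] = (mi, atom.GetIdx())
    if atom_order is None:
        atom_order = sorted(index)
    pos = {mapnum: k for k, mapnum in enumerate(atom_order)}
    n = len(atom_order)
    values = np.zeros((n, n), dtype=float)
    for mapnum, (mi, ai) in index.items():
        if mapnum not in pos:
            raise ValueError(f"atom-map {mapnum} not in supplied atom_order")
        atom = mols[mi].GetAtomWithIdx(ai)
        values[pos[mapnum], pos[mapnum]] = free_valence_electrons(atom)
    for mol in mols:
        for bond in mol.GetBonds():
            m1 = bond.GetBeginAtom().GetAtomMapNum()
            m2 = bond.GetEndAtom().GetAtomMapNum()
            if m1 == 0 or m2 == 0:
                continue
            order = bond.GetBondTypeAsDouble()
            values[pos[m1], pos[m2]] = order
            values[pos[m2], pos[m1]] = order
    return BEMatrix(atom_order=list(atom_order), values=values)


def t_matrix(reaction: MappedReaction) -> TMatrix:
    """R-matrix (product minus reactant BE) and reaction center(s).

    Sides are aligned on the union of atom-map numbers; an atom present on
    only one side contributes an all-zero row on the missing side, so
    appearing/leaving atoms are always part of the center. Connected
    components of the non-zero graph of R are reported as separate centers.
    """
    atom_order = sorted(set(reaction.reactant_index) | set(reaction.product_index))
    be_r = be_matrix(reaction.reactant_mols, atom_order)
    be_p = be_matrix(reaction.product_mols, atom_order)
    r_values = be_p.values - be_r.values

    nonzero_rows = np.any(r_values != 0, axis=1)
    center_atoms = [m for m, nz in zip(atom_order, nonzero_rows) if nz]
    idx = [i for i, nz in enumerate(nonzero_rows) if nz]
    t_values = r_values[np.ix_(idx, idx)]

    # connected components over non-zero off-diagonal entries of R
    adj: dict[int, set[int]] = {m: set() for m in center_atoms}
    for a, i in zip(center_atoms, idx):
        for b, j in zip(center_atoms, idx):
            if i < j and r_values[i, j] != 0:
                adj[a].add(b)
                adj[b].add(a)
    centers: list[list[int]] = []
    unseen = set(center_atoms)
    for seed in center_atoms:
        if seed not in unseen:
            continue
        comp, stack = [], [seed]
        unseen.discard(seed)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in adj[cur]:
                if nb in unseen:
                    unseen.discard(nb)
                    stack.append(nb)
        centers.append(sorted(comp))
    return TMatrix(
        atom_order=atom_order,
        r_values=r_values,
        center_atoms=center_atoms,
        t_values=t_values,
        centers=centers,
    )
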