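"""Deterministic toy reaction sets with known ground truth.

The generator builds atom-mapped reactions constructively — it edits bonds on
a template scaffold and assigns map numbers itself, so the mapping is correct
by construction and no atom-to-atom mapper is involved. Four archetypes are
covered: aromatic C-H hydroxylation of aryl halides, ester hydrolysis,
N-demethylation, and secondary-alcohol oxidation. Every generated reaction
carries its intended class label, its intended reaction-center atom-map set,
and its main product; every generated query carries the expected product set,
enumerated independently by direct graph edits (not by templates), so the
whole pipeline can be checked end to end offline.

Molecules are valence-valid but make no claim to mechanistic realism (the
demethylation archetype, for instance, is written as hydrolytic).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .io import MoleculeRef, ReactionRecord

__all__ = [
    "ARCHETYPES",
    "FixtureSpec",
    "FixtureSet",
    "generate_fixture_set",
    "enumerate_expected_products",
]

ARCHETYPES = (
    "aryl halide hydroxylation",
    "ester hydrolysis",
    "N-demethylation",
    "alcohol oxidation",
)

_LIST_SEP = "|"


@dataclass
class FixtureSpec:
    seed: int = 7
    archetypes: tuple[str, ...] = ARCHETYPES
    n_per_archetype: int = 1
    decoration: tuple[str, ...] = ("Cl", "F", "C")
    n_queries_per_archetype: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype(s): {sorted(unknown)}")


@dataclass
class FixtureSet:
    reactions: list[ReactionRecord]
    ground_truth: pd.DataFrame
    queries: pd.DataFrame
    reactions_frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the same CSV/SMI dialects the real pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reactions": outdir / "reactions.csv",
            "ground_truth": outdir / "ground_truth.csv",
            "queries": outdir / "queries.csv",
            "queries_smi": outdir / "queries.smi",
        }
        self.reactions_frame.to_csv(paths["reactions"], index=False)
        self.ground_truth.to_csv(paths["ground_truth"], index=False)
        self.queries.to_csv(paths["queries"], index=False)
        with open(paths["queries_smi"], "w") as fh:
            for row in self.queries.itertuples():
                fh.write(f"{row.SMILES} {row.QUERY_ID}\n")
        return paths


def _canon(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"generator produced bad SMILES: {smiles}")
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def _sub_atom(sub: str, mapnum: int) -> str:
    return {"Cl": f"[Cl:{mapnum}]", "F": f"[F:{mapnum}]", "C": f"[CH3:{mapnum}]"}[sub]


def _ring(subs: list[str | None], pos1: str, next_map: int) -> tuple[str, int]:
    """Benzene ring with ``pos1`` attached at position 1 and optional
    substituents at positions 2-5; maps 1-6 are the ring, substituent maps
    start at ``next_map``."""
    parts = [f"[c:1]1({pos1})" if pos1 else "[cH:1]1"]
    m = next_map
    for k, sub in zip(range(2, 6), subs):
        if sub is None:
            parts.append(f"[cH:{k}]")
        else:
            parts.append(f"[c:{k}]({_sub_atom(sub, m)})")
            m += 1
    parts.append("[cH:6]1")
    return "".join(parts), m


def _draw_subs(rng: random.Random, alphabet, require_cl: bool) -> list[str | None]:
    while True:
        subs = [rng.choice((None,) + tuple(alphabet)) for _ in range(4)]
        if not require_cl or "Cl" in subs:
            return subs


def _build_hydroxylation(subs) -> dict:
    ring_r, m = _ring(subs, "", 7)
    w = m
    ring_p, _ = _ring(subs, f"[OH:{w}]", 7)
    return {
        "mapped": f"{ring_r}.[OH2:{w}]>>{ring_p}",
        "reactants": [ring_r, f"[OH2:{w}]"],
        "products": [ring_p],
        "center": [1, w],
        "class": "oxidation",
    }


def _build_ester_hydrolysis(subs, alkyl_len: int) -> dict:
    alkyl = "[CH3:10]" if alkyl_len == 1 else "[CH2:10][CH3:11]"
    acyl_r = f"[C:7](=[O:8])[O:9]{alkyl}"
    ring_r, m = _ring(subs, acyl_r, 10 + alkyl_len)
    w = m
    acyl_p = f"[C:7](=[O:8])[OH:{w}]"
    ring_p, _ = _ring(subs, acyl_p, 10 + alkyl_len)
    alcohol = f"[OH:9]{alkyl.replace('[CH3:10]', '[CH3:10]').replace('[CH2:10]', '[CH2:10]')}"
    return {
        "mapped": f"{ring_r}.[OH2:{w}]>>{ring_p}.{alcohol}",
        "reactants": [ring_r, f"[OH2:{w}]"],
        "products": [ring_p, alcohol],
        "center": [7, 9, w],
        "class": "functional group interconversion",
    }


def _build_demethylation(subs) -> dict:
    tail_r = "[CH2:7][N:8]([CH3:9])[CH3:10]"
    ring_r, m = _ring(subs, tail_r, 11)
    w = m
    tail_p = "[CH2:7][NH:8][CH3:9]"
    ring_p, _ = _ring(subs, tail_p, 11)
    return {
        "mapped": f"{ring_r}.[OH2:{w}]>>{ring_p}.[CH3:10][OH:{w}]",
        "reactants": [ring_r, f"[OH2:{w}]"],
        "products": [ring_p, f"[CH3:10][OH:{w}]"],
        "center": [8, 10, w],
        "class": "heteroatom alkylation and arylation",
    }


def _build_oxidation(subs) -> dict:
    tail_r = "[CH:7]([OH:8])[CH3:9]"
    ring_r, _ = _ring(subs, tail_r, 10)
    tail_p = "[C:7](=[O:8])[CH3:9]"
    ring_p, _ = _ring(subs, tail_p, 10)
    return {
        "mapped": f"{ring_r}>>{ring_p}",
        "reactants": [ring_r],
        "products": [ring_p],
        "center": [7, 8],
        "class": "oxidation",
    }


def _build(archetype: str, subs, rng: random.Random) -> dict:
    if archetype == "aryl halide hydroxylation":
        return _build_hydroxylation(subs)
    if archetype == "ester hydrolysis":
        return _build_ester_hydrolysis(subs, alkyl_len=rng.choice((1, 2)))
    if archetype == "N-demethylation":
        return _build_demethylation(subs)
    if archetype == "alcohol oxidation":
        return _build_oxidation(subs)
    raise ValueError(f"unknown archetype {archetype!r}")


# ---------------------------------------------------------------------------
# expected-product oracle: direct graph edits, independent of the template
# machinery
# ---------------------------------------------------------------------------


def _largest_fragment_smiles(mol: Chem.Mol) -> str:
    frags = Chem.MolToSmiles(mol).split(".")
    scored = sorted(
        (Chem.MolFromSmiles(f).GetNumHeavyAtoms(), f) for f in frags
    )
    return scored[-1][1]


def _edit_hydroxylate(mol: Chem.Mol, site: int) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    o = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(site, o, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _edit_hydrolyze(mol: Chem.Mol, c_idx: int, o_idx: int) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    rw.RemoveBond(c_idx, o_idx)
    o_new = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(c_idx, o_new, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _edit_demethylate(mol: Chem.Mol, n_idx: int, c_idx: int) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    rw.RemoveBond(n_idx, c_idx)
    o_new = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(c_idx, o_new, Chem.BondType.SINGLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def _edit_oxidize(mol: Chem.Mol, c_idx: int, o_idx: int) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    rw.GetBondBetweenAtoms(c_idx, o_idx).SetBondType(Chem.BondType.DOUBLE)
    a = rw.GetAtomWithIdx(c_idx)
    a.SetNumExplicitHs(0)
    rw.GetAtomWithIdx(o_idx).SetNumExplicitHs(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


_ORACLE_PATTERNS = {
    "aryl halide hydroxylation": Chem.MolFromSmarts("[c;H1]"),
    "ester hydrolysis": Chem.MolFromSmarts("[CX3](=O)[OX2H0][#6]"),
    "N-demethylation": Chem.MolFromSmarts("[NX3;!$(NC=O)][CH3]"),
    "alcohol oxidation": Chem.MolFromSmarts("[CX4H1]([OX2H])"),
}


def enumerate_expected_products(
    smiles: str, archetypes: tuple[str, ...] = ARCHETYPES
) -> set[str]:
    """All single-round products of the archetype transformations, by direct
    graph editing; the principal (largest-fragment) product per site.

    This enumeration never touches SMARTS templates or the reaction engine,
    so it serves as an independent oracle for them.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    parent = Chem.MolToSmiles(mol)
    out: set[str] = set()

    def add(edited: Chem.Mol) -> None:
        smi = _largest_fragment_smiles(edited)
        if smi != parent:
            out.add(smi)

    for archetype in archetypes:
        patt = _ORACLE_PATTERNS[archetype]
        for match in mol.GetSubstructMatches(patt):
            if archetype == "aryl halide hydroxylation":
                add(_edit_hydroxylate(mol, match[0]))
            elif archetype == "ester hydrolysis":
                add(_edit_hydrolyze(mol, match[0], match[2]))
            elif archetype == "N-demethylation":
                add(_edit_demethylate(mol, match[0], match[1]))
            elif archetype == "alcohol oxidation":
                add(_edit_oxidize(mol, match[0], match[1]))
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_fixture_set(spec: FixtureSpec | None = None) -> FixtureSet:
    """Generate reactions, ground truth, and queries for a fixture spec.

    Deterministic: the same spec (same seed) yields byte-identical tables.
    """
    spec = spec or FixtureSpec()
    rng = random.Random(spec.seed)
    cid_registry: dict[str, str] = {}

    def cid_of(smiles: str) -> str:
        key = _canon(smiles)
        if key not in cid_registry:
            cid_registry[key] = str(900000 + len(cid_registry))
        return cid_registry[key]

    records: list[ReactionRecord] = []
    truth_rows: list[dict] = []
    seen_reactions: set[str] = set()
    for archetype in spec.archetypes:
        made = 0
        attempts = 0
        while made < spec.n_per_archetype:
            attempts += 1
            if attempts > 200 * spec.n_per_archetype:
                raise RuntimeError(
                    f"cannot draw {spec.n_per_archetype} distinct "
                    f"{archetype!r} reactions"
                )
            subs = _draw_subs(
                rng, spec.decoration,
                require_cl=archetype == "aryl halide hydroxylation",
            )
            built = _build(archetype, subs, rng)
            if built["mapped"] in seen_reactions:
                continue
            seen_reactions.add(built["mapped"])
            made += 1
            rxn_id = f"RX{len(records) + 1:04d}"
            r_canon = [_canon(s) for s in built["reactants"]]
            p_canon = [_canon(s) for s in built["products"]]
            records.append(
                ReactionRecord(
                    rxn_id=rxn_id,
                    reaction_smiles=".".join(r_canon) + ">>" + ".".join(p_canon),
                    reactants=[
                        MoleculeRef(s, cid_of(s), "reactant") for s in r_canon
                    ],
                    products=[
                        MoleculeRef(s, cid_of(s), "product") for s in p_canon
                    ],
                    mapped_reaction_smiles=built["mapped"],
                    source="fixture",
                    enzymatic=archetype != "ester hydrolysis",
                )
            )
            truth_rows.append(
                {
                    "RXN_ID": rxn_id,
                    "ARCHETYPE": archetype,
                    "CLASS_LABEL": built["class"],
                    "CENTER_MAPS": _LIST_SEP.join(map(str, built["center"])),
                    "MAIN_PRODUCT": max(
                        p_canon,
                        key=lambda s: (
                            Chem.MolFromSmiles(s).GetNumHeavyAtoms(), s
                        ),
                    ),
                }
            )

    query_rows: list[dict] = []
    seen_queries: set[str] = set()
    for archetype in spec.archetypes:
        made = 0
        attempts = 0
        while made < spec.n_queries_per_archetype:
            attempts += 1
            if attempts > 200 * max(1, spec.n_queries_per_archetype):
                raise RuntimeError(f"cannot draw distinct {archetype!r} queries")
            subs = _draw_subs(
                rng, spec.decoration,
                require_cl=archetype == "aryl halide hydroxylation",
            )
            built = _build(archetype, subs, rng)
            qsmi = _canon(built["reactants"][0])
            if qsmi in seen_queries:
                continue
            seen_queries.add(qsmi)
            made += 1
            expected = sorted(
                enumerate_expected_products(qsmi, spec.archetypes)
            )
            query_rows.append(
                {
                    "QUERY_ID": f"Q{len(query_rows) + 1:03d}",
                    "SMILES": qsmi,
                    "ARCHETYPE": archetype,
                    "CID": cid_of(qsmi),
                    "EXPECTED_PRODUCTS": _LIST_SEP.join(expected),
                }
            )

    from .io import DEFAULT_COLUMNS, CID_SEP

    reactions_frame = pd.DataFrame(
        [
            {
                DEFAULT_COLUMNS["rxn_id"]: r.rxn_id,
                DEFAULT_COLUMNS["reaction_smiles"]: r.reaction_smiles,
                DEFAULT_COLUMNS["mapped_reaction_smiles"]: r.mapped_reaction_smiles,
                DEFAULT_COLUMNS["reactant_cids"]: CID_SEP.join(
                    c or "" for c in r.reactant_cids
                ),
                DEFAULT_COLUMNS["product_cids"]: CID_SEP.join(
                    c or "" for c in r.product_cids
                ),
                DEFAULT_COLUMNS["source"]: r.source,
                DEFAULT_COLUMNS["enzymatic"]: str(r.enzymatic).lower(),
            }
            for r in records
        ]
    )
    return FixtureSet(
        reactions=records,
        ground_truth=pd.DataFrame(truth_rows),
        queries=pd.DataFrame(query_rows),
        reactions_frame=reactions_frame,
    )
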