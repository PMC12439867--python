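import random

import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from ista.annotation import default_fg_library, load_fg_library
from ista.center import sanitize_mapped_reaction
from ista.templates import (
    TemplateError,
    build_template_db,
    changed_atoms,
    expand_atoms,
    extract_template,
)

ESTER_HYDROLYSIS = (
    "[c:1]1([C:7](=[O:8])[O:9][CH3:10])[cH:2][cH:3][cH:4][cH:5][cH:6]1."
    "[OH2:11]"
    ">>[c:1]1([C:7](=[O:8])[OH:11])[cH:2][cH:3][cH:4][cH:5][cH:6]1."
    "[OH:9][CH3:10]"
)
ARYL_SUBSTITUTION = (
    "[Cl:7][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[OH2:8]"
    ">>[OH:8][c:1]1[cH:2][cH:3][cH:4][cH:5][cH:6]1.[ClH:7]"
)
N_DEMETHYLATION = (
    "[CH3:1][N:2]([CH3:3])[CH2:4][CH3:5].[OH2:6]"
    ">>[NH:2]([CH3:3])[CH2:4][CH3:5].[CH3:1][OH:6]"
)


class TestChangedAtoms:
    def test_identity_reaction_empty(self):
        rxn = sanitize_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        assert changed_atoms(rxn) == {}

    def test_ester_hydrolysis_flags_carbonyl_esterO_waterO(self):
        rxn = sanitize_mapped_reaction(ESTER_HYDROLYSIS)
        ch = changed_atoms(rxn)
        flagged_maps = {
            rxn.reactant_mols[mi].GetAtomWithIdx(ai).GetAtomMapNum()
            for mi, atoms in ch.items()
            for ai in atoms
        }
        assert flagged_maps == {7, 9, 11}

    def test_aromatic_substitution_flags_ipso_and_halogen(self):
        rxn = sanitize_mapped_reaction(ARYL_SUBSTITUTION)
        ch = changed_atoms(rxn)
        flagged_maps = {
            rxn.reactant_mols[mi].GetAtomWithIdx(ai).GetAtomMapNum()
            for mi, atoms in ch.items()
            for ai in atoms
        }
        assert flagged_maps == {1, 7, 8}

    def test_atom_without_product_counterpart_is_changed(self):
        rxn = sanitize_mapped_reaction("[CH3:1][C:2](=[O:3])[OH:4]>>[CH4:1]")
        ch = changed_atoms(rxn)
        flagged = {
            rxn.reactant_mols[mi].GetAtomWithIdx(ai).GetAtomMapNum()
            for mi, atoms in ch.items()
            for ai in atoms
        }
        assert {2, 3, 4} <= flagged

    def test_per_property_comparison_oracle(self):
        """changed_atoms agrees with a brute-force per-property comparison."""
        rxn = sanitize_mapped_reaction(N_DEMETHYLATION)

        def props(atom):
            return (
                atom.GetAtomicNum(),
                atom.GetTotalNumHs(),
                atom.GetFormalCharge(),
                atom.GetDegree(),
                atom.GetNumRadicalElectrons(),
                atom.GetIsAromatic(),
                sorted(
                    (
                        n.GetAtomMapNum() or -n.GetAtomicNum(),
                        b.GetBondTypeAsDouble(),
                    )
                    for b in atom.GetBonds()
                    for n in [b.GetOtherAtom(atom)]
                ),
            )

        expected = set()
        for m in rxn.reactant_index:
            r = rxn.reactant_atom(m)
            if m not in rxn.product_index or props(r) != props(
                rxn.product_atom(m)
            ):
                expected.add(m)
        got = {
            rxn.reactant_mols[mi].GetAtomWithIdx(ai).GetAtomMapNum()
            for mi, atoms in changed_atoms(rxn).items()
            for ai in atoms
        }
        assert got == expected


class TestExpandAtoms:
    def test_fg_completion_pulls_full_ester(self):
        mol = Chem.MolFromSmiles("CCOC(C)=O")
        carbonyl_c = next(
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6
            and any(b.GetBondTypeAsDouble() == 2 for b in a.GetBonds())
        )
        expanded = expand_atoms(mol, {carbonyl_c})
        ester_match = mol.GetSubstructMatch(
            Chem.MolFromSmarts("[CX3](=O)[OX2H0][#6]")
        )
        assert set(ester_match) <= expanded

    def test_single_atom_molecule(self):
        mol = Chem.MolFromSmiles("O")
        assert expand_atoms(mol, {0}) == {0}

    def test_radius_one_neighbors_included(self):
        mol = Chem.MolFromSmiles("Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1")
        # ipso = the CH carbon
        ipso = next(
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetTotalNumHs() == 1
        )
        expanded = expand_atoms(mol, {ipso})
        neighbors = {
            n.GetIdx() for n in mol.GetAtomWithIdx(ipso).GetNeighbors()
        }
        assert {ipso} | neighbors <= expanded

    def test_monotone_in_library(self):
        """Growing the expansion library never shrinks the expanded set."""
        mol = Chem.MolFromSmiles("CCOC(C)=O")
        full = default_fg_library()

        class Stripped:
            detection = full.detection
            expansion = []

            def tier(self, name):
                return getattr(self, name)

        small = expand_atoms(mol, {3}, Stripped())
        big = expand_atoms(mol, {3}, full)
        assert small <= big

    def test_changed_outside_molecule_rejected(self):
        with pytest.raises(ValueError):
            expand_atoms(Chem.MolFromSmiles("CC"), {5})


class TestExtractTemplate:
    def test_identity_reaction_skipped(self):
        rxn = sanitize_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]")
        with pytest.raises(TemplateError, match="identity"):
            extract_template(rxn)

    @pytest.mark.parametrize(
        "smi", [ESTER_HYDROLYSIS, ARYL_SUBSTITUTION, N_DEMETHYLATION]
    )
    def test_round_trip_on_source(self, smi):
        """Template applied to its own reactants reproduces the products."""
        rxn = sanitize_mapped_reaction(smi, "t")
        template, subs = extract_template(rxn)  # validate=True round-trips
        assert template.n_reactant_patterns == len(template.reactant_smiles)
        assert subs and all(
            set(s.changed_atoms) <= set(s.expanded_atoms) for s in subs
        )

    def test_substructure_matches_parent(self):
        rxn = sanitize_mapped_reaction(ESTER_HYDROLYSIS, "t")
        _, subs = extract_template(rxn)
        for s in subs:
            parent = Chem.MolFromSmiles(s.parent_smiles)
            patt = Chem.MolFromSmarts(s.substructure_smarts)
            assert parent.HasSubstructMatch(patt)

    def test_canonical_map_renumbering(self):
        """Identical chemistry with different map numbers yields identical
        template SMARTS."""
        a = sanitize_mapped_reaction(
            "[CH3:1][CH:2]([OH:3])[CH3:4]>>[CH3:1][C:2](=[O:3])[CH3:4]", "a"
        )
        b = sanitize_mapped_reaction(
            "[CH3:11][CH:12]([OH:13])[CH3:14]>>[CH3:11][C:12](=[O:13])[CH3:14]",
            "b",
        )
        ta, _ = extract_template(a)
        tb, _ = extract_template(b)
        assert ta.smarts == tb.smarts

    def test_demethylation_template_on_nicotine(self):
        rxn = sanitize_mapped_reaction(N_DEMETHYLATION, "t")
        template, _ = extract_template(rxn)
        r = AllChem.ReactionFromSmarts(template.smarts)
        nicotine = Chem.MolFromSmiles("CN1CCCC1c1cccnc1")
        water = Chem.MolFromSmiles("O")
        products = set()
        for tup in r.RunReactants((nicotine, water)):
            for p in tup:
                Chem.SanitizeMol(p)
                products.add(Chem.MolToSmiles(p))
        nornicotine = Chem.MolToSmiles(Chem.MolFromSmiles("C1CC(c2cccnc2)NC1"))
        assert nornicotine in products


class TestBuildTemplateDb:
    def test_fixture_counts(self, fixture_set, template_db):
        templates, substructures, report = template_db
        assert len(templates) == len(fixture_set.reactions)
        assert len(substructures) >= len(fixture_set.reactions)
        assert report["n_template_failed"] == 0

    def test_empty_input(self):
        templates, substructures, report = build_template_db([])
        assert templates.empty and substructures.empty
        assert report["n_templates"] == 0

    def test_duplicate_reaction_filtered_to_one_template(self, fixture_set):
        rec = fixture_set.reactions[0]
        templates, _, report = build_template_db([rec, rec])
        assert len(templates) == 1
        assert report["n_filtered_out"] == 1

    def test_permutation_invariance(self, fixture_set):
        records = list(fixture_set.reactions)
        shuffled = list(records)
        random.Random(13).shuffle(shuffled)
        t1, s1, _ = build_template_db(records)
        t2, s2, _ = build_template_db(shuffled)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)
        assert s1.to_csv(index=False) == s2.to_csv(index=False)

    def test_unmapped_records_counted(self, fixture_set):
        rec = fixture_set.reactions[0]
        bare = type(rec)(
            rxn_id="nomap",
            reaction_smiles=rec.reaction_smiles,
            reactants=rec.reactants,
            products=rec.products,
            mapped_reaction_smiles=None,
        )
        _, _, report = build_template_db([bare], apply_filter=False)
        assert report["n_unmapped"] == 1 and report["n_templates"] == 0
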