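from collections import Counter

import pytest
from rdkit import Chem

from ista.annotation import (
    CLASS_LABELS,
    annotate_reaction,
    classify_reaction,
    default_fg_library,
    detect_functional_groups,
    find_spectators,
    load_class_rules,
)
from ista.center import sanitize_mapped_reaction, t_matrix


def _classify(smi):
    rxn = sanitize_mapped_reaction(smi)
    return classify_reaction(t_matrix(rxn), rxn)


class TestFGLibrary:
    def test_tier_sizes(self):
        lib = default_fg_library()
        assert len(lib.detection) == 107
        assert len(lib.expansion) == 30

    def test_names_unique_within_tier(self):
        lib = default_fg_library()
        for tier in (lib.detection, lib.expansion):
            names = [n for n, _ in tier]
            assert len(names) == len(set(names))

    @pytest.mark.parametrize(
        "smiles, present, absent",
        [
            ("CCO", ["primary alcohol"], ["ester", "ketone"]),
            ("C", [], ["primary alcohol"]),
            # ester oxygen is deliberately excluded from the ether pattern
            ("CCOC(C)=O", ["ester"], ["ether", "carboxylic acid"]),
            ("CC(C)O", ["secondary alcohol"], ["primary alcohol"]),
            ("Oc1ccccc1", ["phenol", "arene"], ["primary alcohol"]),
            ("CCN(CC)CC", ["tertiary amine"], ["amide"]),
            ("CCOP(=S)(OCC)Oc1ccccc1", ["phosphorothioate"], []),
        ],
    )
    def test_detection_examples(self, smiles, present, absent):
        found = detect_functional_groups(Chem.MolFromSmiles(smiles))
        for name in present:
            assert name in found, f"{name} not found in {smiles}: {dict(found)}"
        for name in absent:
            assert name not in found

    def test_counts_are_match_counts(self):
        found = detect_functional_groups(Chem.MolFromSmiles("OCCCCO"))
        assert found["primary alcohol"] == 2


class TestClassification:
    @pytest.mark.parametrize(
        "smi, label",
        [
            # secondary alcohol -> ketone
            (
                "[CH3:1][CH:2]([OH:3])[CH3:4]>>[CH3:1][C:2](=[O:3])[CH3:4]",
                "oxidation",
            ),
            # mirror image
            (
                "[CH3:1][C:2](=[O:3])[CH3:4]>>[CH3:1][CH:2]([OH:3])[CH3:4]",
                "reduction",
            ),
            # acid + amine -> amide
            (
                "[CH3:1][C:2](=[O:3])[OH:4].[NH2:5][CH3:6]"
                ">>[CH3:1][C:2](=[O:3])[NH:5][CH3:6].[OH2:4]",
                "acylation",
            ),
            # ester + water -> acid + alcohol
            (
                "[CH3:1][C:2](=[O:3])[O:4][CH3:5].[OH2:6]"
                ">>[CH3:1][C:2](=[O:3])[OH:6].[OH:4][CH3:5]",
                "functional group interconversion",
            ),
            # Diels-Alder cycloaddition: two new C-C bonds, redox-neutral
            (
                "[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
                ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:6][CH2:5]1",
                "C-C coupling",
            ),
            # O-silylation: protection
            (
                "[CH3:1][OH:2].[Si:3]([Cl:4])([CH3:5])([CH3:6])[CH3:7]"
                ">>[CH3:1][O:2][Si:3]([CH3:5])([CH3:6])[CH3:7].[ClH:4]",
                "protection",
            ),
            # identity -> miscellaneous
            ("[CH4:1]>>[CH4:1]", "miscellaneous"),
        ],
    )
    def test_rule_cascade(self, smi, label):
        assert _classify(smi) == label

    def test_totality_on_fixtures(self, fixture_set):
        for rec in fixture_set.reactions:
            rxn = sanitize_mapped_reaction(rec.mapped_reaction_smiles, rec.rxn_id)
            label = classify_reaction(t_matrix(rxn), rxn)
            assert label in CLASS_LABELS

    def test_archetypes_map_to_intended_labels(self, fixture_set):
        truth = fixture_set.ground_truth.set_index("RXN_ID")
        for rec in fixture_set.reactions:
            rxn = sanitize_mapped_reaction(rec.mapped_reaction_smiles, rec.rxn_id)
            label = classify_reaction(t_matrix(rxn), rxn)
            assert label == truth.loc[rec.rxn_id, "CLASS_LABEL"]

    def test_rule_order_is_configuration(self):
        rules = load_class_rules()
        assert rules["rules"][0] == "protection"
        assert "oxidation" in rules["rules"]


class TestSpectators:
    def test_unchanged_water_flagged(self):
        rxn = sanitize_mapped_reaction(
            "[CH3:1][OH:2].[OH2:9]>>[CH2:1]=[O:2].[OH2:9]"
        )
        assert find_spectators(rxn, t_matrix(rxn)) == [
            ("reactant", 1),
            ("product", 1),
        ]

    def test_both_components_changed_empty(self):
        rxn = sanitize_mapped_reaction(
            "[CH3:1][Br:2].[OH2:3]>>[CH3:1][OH:3].[BrH:2]"
        )
        assert find_spectators(rxn, t_matrix(rxn)) == []

    def test_invariant_under_molecule_reordering(self):
        a = sanitize_mapped_reaction(
            "[CH3:1][OH:2].[OH2:9]>>[CH2:1]=[O:2].[OH2:9]"
        )
        b = sanitize_mapped_reaction(
            "[OH2:9].[CH3:1][OH:2]>>[OH2:9].[CH2:1]=[O:2]"
        )
        names_a = {side for side, _ in find_spectators(a, t_matrix(a))}
        names_b = {side for side, _ in find_spectators(b, t_matrix(b))}
        assert names_a == names_b == {"reactant", "product"}


class TestAnnotateReaction:
    def test_nos_in_center_matches_t_matrix(self, fixture_set):
        for rec in fixture_set.reactions:
            rxn = sanitize_mapped_reaction(rec.mapped_reaction_smiles, rec.rxn_id)
            t = t_matrix(rxn)
            ann = annotate_reaction(rxn, t=t)
            nos = {7, 8, 16}
            expect = any(
                (
                    rxn.reactant_atom(m)
                    if m in rxn.reactant_index
                    else rxn.product_atom(m)
                ).GetAtomicNum()
                in nos
                for m in t.center_atoms
            )
            assert ann.nos_in_center == expect

    def test_counts_and_scaffold(self):
        rxn = sanitize_mapped_reaction(
            "[c:1]1([CH3:7])[cH:2][cH:3][cH:4][cH:5][cH:6]1.[OH2:8]"
            ">>[c:1]1([CH2:7][OH:8])[cH:2][cH:3][cH:4][cH:5][cH:6]1"
        )
        ann = annotate_reaction(rxn)
        assert ann.n_reactants == 2 and ann.n_products == 1
        assert ann.has_scaffold  # benzene ring present
        assert ann.ring_in_center is False  # benzylic oxidation only
        assert isinstance(ann.fg_reactants, Counter)

    def test_ring_changed_on_ring_opening(self):
        rxn = sanitize_mapped_reaction(
            "[CH2:1]1[CH2:2][O:3]1.[OH2:4]"
            ">>[OH:4][CH2:1][CH2:2][OH:3]"
        )
        ann = annotate_reaction(rxn)
        assert ann.ring_changed
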