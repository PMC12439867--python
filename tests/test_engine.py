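import pandas as pd
import pytest
from rdkit import Chem

from ista.center import sanitize_mapped_reaction
from ista.engine import (
    QueryCompound,
    annotate_known,
    apply_template,
    dedup_key,
    largest_fragment,
    screen_templates,
    transform,
)
from ista.templates import extract_template, templates_to_frame

PENTACHLOROBENZENE = "Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1"
PENTACHLOROPHENOL = Chem.MolToSmiles(
    Chem.MolFromSmiles("Oc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl")
)

# aromatic C-H hydroxylation extracted from a chloroarene toy reaction
HYDROXYLATION = (
    "[cH:1]1[c:2]([Cl:7])[cH:3][cH:4][cH:5][cH:6]1.[OH2:8]"
    ">>[c:1]1([OH:8])[c:2]([Cl:7])[cH:3][cH:4][cH:5][cH:6]1"
)


@pytest.fixture(scope="module")
def hydroxylation_template():
    rxn = sanitize_mapped_reaction(HYDROXYLATION, "fig1")
    template, subs = extract_template(rxn)
    return template, subs


class TestDedupKey:
    def test_dialect_invariance(self):
        assert dedup_key("OCC") == dedup_key("C(O)C")

    def test_largest_fragment_drops_leaving_group(self):
        assert largest_fragment("Cl.Oc1ccccc1") == Chem.MolToSmiles(
            Chem.MolFromSmiles("Oc1ccccc1")
        )
        assert dedup_key("Cl.Oc1ccccc1") == dedup_key("Oc1ccccc1")

    def test_distinct_structures_distinct_keys(self):
        assert dedup_key("CCO") != dedup_key("CC=O")


class TestScreenAndApply:
    def test_fig1_worked_example(self, hydroxylation_template):
        """Hydroxylation template on pentachlorobenzene: exactly one unique
        product, pentachlorophenol, by structure identity."""
        template, subs = hydroxylation_template
        frame = templates_to_frame([template])
        products, counts = apply_template(
            QueryCompound("pcb", PENTACHLOROBENZENE), frame.iloc[0]
        )
        assert products == {PENTACHLOROPHENOL}
        assert counts["n_unsanitizable"] == 0
        assert dedup_key(next(iter(products))) == dedup_key(PENTACHLOROPHENOL)

    def test_screen_returns_matching_template(
        self, hydroxylation_template, template_db
    ):
        from ista.templates import substructures_to_frame

        _, subs = hydroxylation_template
        s_frame = substructures_to_frame(subs)
        hits = screen_templates(PENTACHLOROBENZENE, s_frame)
        assert [t for _, t in hits] == ["T_fig1"]

    def test_methane_matches_nothing(self, template_db):
        _, substructures, _ = template_db
        assert screen_templates("C", substructures) == []

    def test_non_matching_template_empty(self, hydroxylation_template):
        template, _ = hydroxylation_template
        frame = templates_to_frame([template])
        products, _ = apply_template(QueryCompound("q", "CCCC"), frame.iloc[0])
        assert products == set()

    def test_single_only_policy_skips_multi_reactant(
        self, hydroxylation_template
    ):
        template, _ = hydroxylation_template
        frame = templates_to_frame([template])
        products, _ = apply_template(
            QueryCompound("pcb", PENTACHLOROBENZENE),
            frame.iloc[0],
            multi_reactant_policy="single_only",
        )
        assert products == set()


class TestTransform:
    def test_products_match_fixture_ground_truth(
        self, template_db, fixture_set, fixture_queries
    ):
        templates, substructures, _ = template_db
        frame, summary = transform(fixture_queries, templates, substructures)
        for row in fixture_set.queries.itertuples():
            got = sorted(frame.loc[frame.query_id == row.QUERY_ID, "product_smiles"])
            expected = sorted(row.EXPECTED_PRODUCTS.split("|"))
            assert got == expected, row.QUERY_ID

    def test_screen_equals_brute_force(
        self, template_db, fixture_queries
    ):
        """Screen-then-apply product sets equal exhaustive all-template
        application (soundness and completeness of screening)."""
        templates, substructures, _ = template_db
        screened, _ = transform(
            fixture_queries, templates, substructures, use_screen=True
        )
        brute, _ = transform(
            fixture_queries, templates, substructures, use_screen=False
        )
        key = ["query_id", "dedup_key"]
        assert sorted(map(tuple, screened[key].values.tolist())) == sorted(
            map(tuple, brute[key].values.tolist())
        )

    def test_deterministic_byte_identical(self, template_db, fixture_queries):
        templates, substructures, _ = template_db
        a, _ = transform(fixture_queries, templates, substructures)
        b, _ = transform(fixture_queries, templates, substructures)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_empty_query_list(self, template_db):
        templates, substructures, _ = template_db
        frame, summary = transform([], templates, substructures)
        assert frame.empty and summary["n_queries"] == 0

    def test_parent_excluded(self, template_db, fixture_queries):
        templates, substructures, _ = template_db
        frame, _ = transform(fixture_queries, templates, substructures)
        for row in frame.itertuples():
            assert row.dedup_key != dedup_key(row.query_smiles)

    def test_global_dedup_not_larger_than_per_query(
        self, template_db, fixture_queries
    ):
        templates, substructures, _ = template_db
        per_query, s1 = transform(
            fixture_queries, templates, substructures, dedup_scope="per_query"
        )
        global_, s2 = transform(
            fixture_queries, templates, substructures, dedup_scope="global"
        )
        assert len(global_) <= len(per_query)
        assert (
            s1["n_unique_products_global"] == s2["n_unique_products_global"]
        )

    def test_dedup_idempotent(self, template_db, fixture_queries):
        templates, substructures, _ = template_db
        frame, summary = transform(fixture_queries, templates, substructures)
        again = frame.drop_duplicates(["query_id", "dedup_key"])
        assert len(again) == len(frame)


class TestAnnotateKnown:
    def test_snapshot_match_and_novel(self, tmp_path):
        products = pd.DataFrame(
            {
                "query_id": ["q", "q"],
                "query_smiles": [PENTACHLOROBENZENE] * 2,
                "product_smiles": [PENTACHLOROPHENOL, "OCCCCCO"],
                "dedup_key": [
                    dedup_key(PENTACHLOROPHENOL),
                    dedup_key("OCCCCCO"),
                ],
                "rxn_id": ["r", "r"],
                "template_id": ["t", "t"],
                "known_cid": ["", ""],
            }
        )
        snap = tmp_path / "snapshot.tsv"
        snap.write_text(f"CID\tSMILES\n992\t{PENTACHLOROPHENOL}\n")
        annotated, report = annotate_known(products, snap)
        assert annotated.loc[0, "known_cid"] == "992"
        assert annotated.loc[1, "known_cid"] == ""
        assert report["n_known"] == 1 and report["match_rate"] == 0.5

    def test_missing_snapshot_skips_with_warning(self, tmp_path):
        products = pd.DataFrame(columns=["dedup_key"])
        _, report = annotate_known(products, tmp_path / "absent.tsv")
        assert report["skipped"]
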