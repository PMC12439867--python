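# ista — in-silico transformation analysis

`ista` predicts the transformation (metabolic/degradation) products of a
query chemical from a database of reaction templates learned from
atom-mapped reaction data. It is aimed at exposomics and toxicology groups
who need plausible, mechanistically grounded product hypotheses for
xenobiotics — pesticides, drugs, industrial chemicals — to expand screening
panels and annotate untargeted mass-spectrometry data.

## What it does

Given a table of reactions with atom-to-atom mapped reaction SMILES
(mapping is consumed as precomputed input; `ista` never computes it):

1. **Filter** — reactions with missing reactant/product compound identifiers
   (CIDs) are dropped, and reactions whose per-side CID multisets coincide
   with an earlier reaction are removed as redundant.
2. **Reaction-center detection** — each side of a sanitized mapped reaction
   is encoded as a bond–electron (BE) matrix over mapped heavy atoms:
   diagonal entries hold free (non-bonded) valence electrons, off-diagonal
   entries hold bond orders (0 none, 1 single, 1.5 aromatic, 2 double,
   3 triple). The R-matrix `R = BE(products) − BE(reactants)`, aligned on
   atom-map numbers, is non-zero exactly at the atoms whose bonding changed;
   deleting its all-zero rows/columns gives the T-matrix whose atoms are the
   reaction center.
3. **Annotation** — an ordered, configurable rule cascade assigns one of ten
   reaction classes (acylation, aromatic heterocycle formation, C–C
   coupling, heteroatom alkylation and arylation, functional group addition,
   functional group interconversion, protection, deprotection, oxidation,
   reduction; fall-through: miscellaneous). Functional groups are detected
   with a 107-pattern SMARTS library; N/O/S participation in the center,
   ring involvement, Murcko scaffolds, and spectator molecules are recorded.
4. **Template extraction** — atoms whose local properties (element, H count,
   charge, degree, radicals, aromaticity, neighbor identity) differ between
   their reactant and product instances are expanded by radius 1 and
   completed with any of 30 expansion-tier functional groups touching them;
   the expanded context and its product image are serialized as a forward
   reaction SMARTS, validated by re-applying it to its own reactants.
5. **Transformation analysis** — a query SMILES is screened against the
   reactive-substructure database, matching templates are applied with
   RDKit `RunReactants`, each embedding is reduced to its largest covalent
   fragment, canonicalized, and deduplicated by InChIKey. Products are
   annotated against a local known-compound snapshot (CID ↔ InChIKey) and
   flagged when they fall in the adverse-direction top 1st percentile of a
   reference compound set for at least one descriptor.

## Worked example

```python
from ista import (QueryCompound, apply_template, extract_template,
                  sanitize_mapped_reaction)
from ista.templates import templates_to_frame

# a toy chloroarene hydroxylation, atom-mapped by construction
mapped = sanitize_mapped_reaction(
    "[cH:1]1[c:2]([Cl:7])[cH:3][cH:4][cH:5][cH:6]1.[OH2:8]"
    ">>[c:1]1([OH:8])[c:2]([Cl:7])[cH:3][cH:4][cH:5][cH:6]1", "demo")
template, substructures = extract_template(mapped)
print(template.smarts)
# [#6;a;+0:1]:[#6;a;H1;+0:2]:[#6;a;+0:3].[#8;A;H2;+0:4]
#   >>[#6;a:1]:[#6;a;H0;+0:2](:[#6;a:3])-[#8;A;H1;+0:4]

products, counts = apply_template(
    QueryCompound("pcb", "Clc1c(Cl)c(Cl)c(Cl)c(Cl)c1"),  # pentachlorobenzene
    templates_to_frame([template]).iloc[0])
print(products)
# {'Oc1c(Cl)c(Cl)c(Cl)c(Cl)c1Cl'}
```

Pentachlorobenzene has a single aromatic C–H, so the hydroxylation template
yields exactly one unique product — pentachlorophenol. The template's
reactant pattern pins the reacting atoms (an aromatic CH, a water oxygen)
while leaving the flanking ring atoms loose, which is why it generalizes
from the unsubstituted toy reaction to the fully chlorinated query.

The same stages are available as scikit-learn estimators
(`TransformationEnumerator.fit(reactions).transform(smiles_list)`,
`ExtremeFlagger.fit(reference).transform(products)`) and as a CLI:

```bash
ista fixtures --seed 7 --n-per-archetype 2 --out run/
ista filter --reactions run/reactions.csv --out run/filtered.csv
ista build-templates --reactions run/filtered.csv \
     --templates run/templates.csv --substructures run/substructures.csv
ista transform --templates run/templates.csv \
     --substructures run/substructures.csv --queries run/queries.smi \
     --out run/products.csv
ista prioritize --products run/products.csv --reference ref.csv \
     --out run/prioritized.csv
```

Every stage writes a JSON run-report next to its artifact with read/kept/
skipped counts.

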