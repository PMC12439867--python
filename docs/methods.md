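# Methods

## Scope and assumptions

`ista` operates on reactions that already carry an atom-to-atom mapping
(daylight `[C:1]` syntax). Mapping quality is the caller's responsibility;
the package validates only that product-side map numbers also occur on the
reactant side (atoms are tracked from substrates to products) and that map
numbers are unique within a side. Unmapped atoms are tolerated: on the
reactant side they are treated as untracked context, and unmapped product
atoms adjacent to the transformed context are treated as created atoms.
Stereochemistry is preserved where the input encodes it but never inferred,
and the matrices do not track stereocenter changes.

## Bond–electron matrices and reaction centers

Each reaction side is encoded as one combined square matrix over its mapped
heavy atoms, block-structured by molecule. Off-diagonal entries are bond
orders with aromatic bonds as 1.5; diagonal entries are free (non-bonded)
valence electrons, computed as

    outer-shell electrons of the element − formal charge − Σ bond orders,

with hydrogens counting one bond order each (the standard Dugundji–Ugi
reading; water's lone oxygen scores 6 − 0 − 2 = 4). The R-matrix is the
product-side matrix minus the reactant-side matrix after aligning both on
the union of atom-map numbers; an atom present on only one side gets an
all-zero row on the missing side, so appearing/leaving atoms always join
the center. Atoms with any non-zero R row form the reaction center;
connected components of the non-zero off-diagonal graph are reported as
separate centers. All matrix values are integer multiples of 0.5, which
binary floating point represents exactly, so zero/non-zero tests need no
tolerance. A deliberate consequence of the definition: an atom whose heavy-
atom bonds and free-electron count are both unchanged (e.g. a pure proton
tautomer shift between two otherwise-identical environments) does not
register in R; the changed-atom comparison used for templates (below) is
the stricter instrument and does catch hydrogen-count changes.

## Classification

The ten-class assignment is an ordered rule cascade; the order (and the
protecting-group patterns used by the protection/deprotection rules) ships
as editable configuration in `data/class_rules.yaml`, while the predicate
bodies are code keyed by rule name. Defaults, in order: protection,
deprotection, oxidation, reduction, aromatic heterocycle formation,
acylation, C–C coupling, heteroatom alkylation and arylation, functional
group addition, functional group interconversion; anything else (including
identity reactions with an empty center) is miscellaneous. Oxidation and
reduction compare an oxidation-state proxy summed over center carbons
(bond order to N/O/S/halogen minus hydrogen count, product minus
reactant). Acylation requires a newly formed bond from a carbonyl carbon to
N, S, or an alkoxy oxygen — a hydrolysis water oxygen (no other heavy
neighbor) does not qualify, which is what routes ester hydrolysis to
functional group interconversion instead. These predicates are heuristics
calibrated on the fixture archetypes; reordering the cascade changes the
labels of reactions satisfying several predicates, which is exactly why the
order is data.

Functional-group detection uses a 107-entry SMARTS library; template
expansion uses a separate 30-entry tier of core groups. Both are authored
for this package and ship as a TSV (`data/functional_groups.tsv`) that users
can edit or replace; the tier sizes follow the two-tier design the pipeline
expects, not any canonical external list. The ether pattern deliberately
requires both carbons sp3, so ester oxygens do not double-count as ethers.
"Has scaffold" means a non-empty Murcko scaffold (ring systems plus
linkers) on at least one participant.

## Template extraction

An atom is *changed* when element, total hydrogens, formal charge, heavy
degree, radical electrons, aromaticity, or neighbor identity differ between
its reactant and product instances, or when it lacks a product counterpart.
Neighbor identity is the multiset of (neighbor, bond order) pairs where a
mapped neighbor is identified by its map number — so an acyl oxygen swapped
for a water oxygen changes the carbonyl carbon even though both neighbors
are oxygens — and an unmapped neighbor by its element. The changed set is
expanded by one bond radius, then completed with every expansion-tier
functional group sharing at least one atom with the expanded set (single
pass; the completion set is not re-expanded).

The template is a forward reaction SMARTS. Reactant-side atom queries are
strict on changed atoms (element, aromaticity, H count, charge) and loose
on context atoms (element, aromaticity, charge); product-side queries pin
H count and charge only for changed and created atoms, so the engine
inherits context-atom state from the query molecule rather than from the
source reaction. This asymmetry is what lets a template extracted from an
unsubstituted toy reaction apply cleanly to decorated analogues. Atom maps
are renumbered 1..k in canonical output order so identical patterns from
different reactions serialize identically (optional dedup; off by default
to preserve per-reaction provenance). Every template is validated by
round-trip: applied to its own (map-stripped) source reactants, some
embedding must reproduce all covered source products by canonical identity,
or the reaction is skipped and counted. The per-reactant reactive-site
SMARTS stored for screening is byte-identical to that reactant's pattern in
the template, which makes screening sound and complete with respect to
template applicability by construction.

## Product enumeration

Screening returns the templates whose reactive-site pattern matches the
query; each is applied with `RunReactants`. For multi-reactant templates
the query is substituted into every role it matches and the remaining roles
are filled with the source reaction's own co-reactants (policy `fill`;
`single_only` skips such templates). Every successful embedding is reduced
to its *principal product*: the largest covalent fragment of the combined
product set (ties broken by canonical SMILES order). This one convention
discards leaving groups and salts (HCl from an aromatic substitution) and
selects the acid over the alcohol in an ester hydrolysis; the discarded
minor fragments are a known information loss, accepted for a deterministic,
single-valued product notion. Products failing sanitization are dropped and
counted, not repaired. Deduplication keys on the full InChIKey of the
principal fragment; products identical to the parent are excluded. One
transformation round is performed; depth is not iterated. Unique-product
counts are reported both per query and globally, since the two notions
differ whenever queries share products.

Known-compound annotation is an exact InChIKey join against a local
CID ↔ SMILES/InChIKey snapshot; a live lookup service can be wired behind
the same interface but is never required or contacted by default.

## Prioritization

The default descriptor plugin computes nine deterministic physicochemical
descriptors with RDKit (molecular weight, Crippen logP, TPSA, H-bond
donors/acceptors, rotatable bonds, aromatic rings, fraction Csp3, QED).
Trained ADME/Tox predictors can be registered as alternative plugins; none
is bundled. Percentiles are empirical with midpoint tie handling
(`100·(#less + ½·#equal)/n`) against the reference distribution only —
products never contaminate the reference. A product is flagged when, for at
least one descriptor, it lies in the adverse-direction top `threshold`
percent (default 1). The adverse direction per descriptor is explicit
configuration; defaults treat size/lipophilicity-type descriptors as
higher-worse and QED/Fsp3 as lower-worse, which is a screening convention,
not a toxicological claim. Flagging is monotone in the threshold and
invariant under monotone rescaling of any descriptor applied to both sides.

## Synthetic fixtures

The fixture generator builds atom-mapped reactions constructively — it
edits bonds on decorated benzene scaffolds and assigns map numbers itself —
so mappings are correct by construction and no mapping tool is involved.
Four archetypes: aromatic C–H hydroxylation of chloroarenes, ester
hydrolysis (benzoate esters, so the acid is the principal fragment),
hydrolytic N-demethylation (written as R₂N–CH₃ + H₂O → R₂N–H + CH₃OH to
stay valence-balanced over heavy atoms without modelling the oxidative
mechanism), and secondary-alcohol oxidation (the reduced hydrogen
counterpart is left implicit). Ring decorations (Cl, F, CH₃ over four
positions) are drawn from a seeded RNG; the same seed yields byte-identical
tables. Each reaction carries its intended class label, center atom-map
set, and main product; each query carries its expected product set,
enumerated by direct graph edits on the query molecule — an oracle that
shares no code path with the SMARTS/`RunReactants` engine it checks.

What the fixtures do *not* emulate: mapping noise and mapping errors,
unbalanced or ill-formed crowd-sourced reactions, stereochemistry,
multi-center reactions, charged species, and the scale (10⁴–10⁵ reactions)
of a real reaction archive. Green fixtures therefore demonstrate the
correctness of the machinery (matrix algebra, expansion, serialization,
screening, application, dedup), not the empirical yield of any particular
archive.

## Problem sizes and defaults

The test suite and the acceptance script run on 4–20 reactions and 4–12
queries per invocation, a scale at which every stage is exhaustively
checkable against ground truth; the acceptance script uses five reactions
and three queries per archetype, a synthetic uniform reference of n=1000
for flag calibration, and 4000 probe points. Defaults throughout reproduce
the pipeline's stated settings: expansion radius 1, one transformation
round, 1st-percentile flag threshold, per-query dedup scope, `fill`
multi-reactant policy.

## Known limitations

- Templates are as general as their context is loose: reactions whose
  reactivity depends on features outside the radius-1 + functional-group
  context will over-apply.
- The principal-fragment convention reports one product per embedding;
  workflows needing both hydrolysis fragments must re-run with the
  complementary fragment as query or post-process the embedding output.
- The classifier is a heuristic cascade; its labels are reproducible but
  not a substitute for curated reaction ontologies.
- InChIKey identity collapses tautomers to the InChI standard form and
  distinguishes stereoisomers; either behavior may differ from a given
  database's compound-identity policy.
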