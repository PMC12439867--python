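# Ordered rule cascade for the ten-class reaction classification.
# The first enabled rule whose predicate fires assigns the label; reactions
# matching nothing fall through to "miscellaneous". Reordering or disabling
# entries here recalibrates the classifier without code changes; the
# predicates themselves are implemented in ista.annotation keyed by rule name.
rules:
  - protection
  - deprotection
  - oxidation
  - reduction
  - aromatic heterocycle formation
  - acylation
  - C-C coupling
  - heteroatom alkylation and arylation
  - functional group addition
  - functional group interconversion

# Protecting-group substructures used by the protection/deprotection rules.
protecting_groups:
  silyl ether: "[OX2]([#6])[Si]"
  acetal: "[CX4]([OX2][#6])([OX2][#6])"
  benzyl ether: "[c][CH2][OX2][CX4]"
  tetrahydropyranyl ether: "C1CCOC(O1)"
  tert-butyl carbamate: "[NX3][CX3](=O)[OX2]C(C)(C)C"
  tert-butyl ester: "[CX3](=O)[OX2]C(C)(C)C"
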