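name	smarts	tier
alkene	[CX3]=[CX3]	detection
alkyne	[CX2]#[CX2]	detection
arene	c1ccccc1	detection
primary alcohol	[CX4H2][OX2H]	detection
secondary alcohol	[CX4H1]([#6])[OX2H]	detection
tertiary alcohol	[CX4]([#6])([#6])([#6])[OX2H]	detection
phenol	[c][OX2H]	detection
enol	[CX3]=[CX3][OX2H]	detection
ether	[OX2]([CX4])[CX4]	detection
aryl ether	[c][OX2][#6]	detection
epoxide	C1OC1	detection
peroxide	[OX2][OX2]	detection
hydroperoxide	[OX2H][OX2]	detection
aldehyde	[CX3H1](=O)[#6]	detection
ketone	[#6][CX3](=O)[#6]	detection
acetal	[CX4]([OX2][#6])([OX2][#6])	detection
hemiacetal	[CX4]([OX2H])([OX2][#6])	detection
carboxylic acid	[CX3](=O)[OX2H1]	detection
carboxylate anion	[CX3](=O)[O-]	detection
ester	[CX3](=O)[OX2H0][#6]	detection
lactone	[C;R](=O)[O;R]	detection
anhydride	[CX3](=O)[OX2][CX3](=O)	detection
acyl halide	[CX3](=O)[F,Cl,Br,I]	detection
carbonate ester	[#6][OX2][CX3](=O)[OX2][#6]	detection
primary amine	[NX3;H2;!$(NC=O);!$(N=O)][#6]	detection
secondary amine	[NX3;H1;!$(NC=O);!$(N=O)]([#6])[#6]	detection
tertiary amine	[NX3;H0;!$(NC=O);!$(N=O);!$(N[O-])]([#6])([#6])[#6]	detection
quaternary ammonium	[NX4+]	detection
aromatic amine	[c][NX3;H2]	detection
amide	[NX3][CX3](=O)[#6]	detection
lactam	[N;R][C;R](=O)	detection
imide	[CX3](=O)[NX3][CX3](=O)	detection
nitrile	[NX1]#[CX2]	detection
nitro	[NX3+](=O)[O-]	detection
nitroso	[NX2]=[OX1]	detection
N-oxide	[NX4+,nX3+][O-]	detection
nitrate ester	[OX2][NX3+](=O)[O-]	detection
azide	[NX2]=[NX2+]=[NX1-]	detection
azo	[#6][NX2]=[NX2][#6]	detection
hydrazine	[NX3][NX3]	detection
hydrazone	[NX3][NX2]=[CX3]	detection
imine	[CX3]=[NX2][#6,#1;!$([#7][OX2H])]	detection
oxime	[CX3]=[NX2][OX2H]	detection
oxime ether	[CX3]=[NX2][OX2][#6]	detection
hydroxylamine	[NX3][OX2H]	detection
amidine	[NX3][CX3]=[NX2]	detection
guanidine	[NX3][CX3](=[NX2])[NX3]	detection
carbamate	[NX3][CX3](=O)[OX2]	detection
urea	[NX3][CX3](=O)[NX3]	detection
isocyanate	[NX2]=[CX2]=[OX1]	detection
cyanamide	[NX3][CX2]#[NX1]	detection
enamine	[NX3][CX3]=[CX3]	detection
aziridine	C1NC1	detection
thiol	[#6][SX2H]	detection
thioether	[#6][SX2]([#6])	detection
disulfide	[SX2][SX2]	detection
sulfoxide	[SX3](=O)([#6])[#6]	detection
sulfone	[SX4](=O)(=O)([#6])[#6]	detection
sulfonamide	[SX4](=O)(=O)[NX3]	detection
sulfonic acid	[SX4](=O)(=O)[OX2H]	detection
sulfonate ester	[SX4](=O)(=O)[OX2][#6]	detection
sulfate ester	[OX2][SX4](=O)(=O)[OX2]	detection
sulfonyl halide	[SX4](=O)(=O)[F,Cl,Br,I]	detection
thioamide	[NX3][CX3]=[SX1]	detection
thioester	[SX2][CX3]=[OX1]	detection
thiourea	[NX3][CX3](=S)[NX3]	detection
isothiocyanate	[NX2]=[CX2]=[SX1]	detection
thiocyanate	[SX2][CX2]#[NX1]	detection
thione	[#6][CX3]=[SX1]	detection
phosphate ester	[OX2][PX4](=O)([OX2])[OX2]	detection
phosphonate	[#6][PX4](=O)([OX2])[OX2]	detection
phosphine	[PX3]([#6])([#6])[#6]	detection
phosphine oxide	[PX4](=O)([#6])([#6])[#6]	detection
phosphorothioate	[PX4](=S)([OX2])([OX2])[OX2]	detection
phosphoramidate	[NX3][PX4](=[O,S])([OX2])[OX2]	detection
alkyl fluoride	[CX4][F]	detection
alkyl chloride	[CX4][Cl]	detection
alkyl bromide	[CX4][Br]	detection
alkyl iodide	[CX4][I]	detection
aryl fluoride	[c][F]	detection
aryl chloride	[c][Cl]	detection
aryl bromide	[c][Br]	detection
aryl iodide	[c][I]	detection
vinyl halide	[CX3]=[CX3][F,Cl,Br,I]	detection
trifluoromethyl	[CX4](F)(F)F	detection
furan	c1ccoc1	detection
thiophene	c1ccsc1	detection
pyrrole	c1cc[nH]c1	detection
imidazole	c1cnc[nH]1	detection
pyrazole	c1cc[nH]n1	detection
oxazole	c1ocnc1	detection
isoxazole	c1oncc1	detection
thiazole	c1scnc1	detection
pyridine	c1ccncc1	detection
pyrimidine	c1cncnc1	detection
pyrazine	c1cnccn1	detection
triazole	c1nc[nH]n1	detection
tetrazole	c1nnn[nH]1	detection
indole	c1ccc2[nH]ccc2c1	detection
quinoline	c1ccc2ncccc2c1	detection
piperidine	C1CCNCC1	detection
piperazine	C1CN(CC(N1))	detection
morpholine	C1COCCN1	detection
pyrrolidine	C1CCNC1	detection
tetrahydrofuran	C1CCOC1	detection
silyl ether	[OX2]([#6])[Si]	detection
benzyl ether	[c][CH2][OX2][#6]	detection
alkene	[CX3]=[CX3]	expansion
alkyne	[CX2]#[CX2]	expansion
hydroxyl	[#6][OX2H]	expansion
ether	[OX2]([#6])[#6]	expansion
epoxide	C1OC1	expansion
peroxide	[OX2][OX2]	expansion
aldehyde	[CX3H1](=O)[#6]	expansion
ketone	[#6][CX3](=O)[#6]	expansion
carboxylic acid	[CX3](=O)[OX2H1]	expansion
ester	[CX3](=O)[OX2H0][#6]	expansion
anhydride	[CX3](=O)[OX2][CX3](=O)	expansion
amide	[NX3][CX3](=O)[#6]	expansion
amine	[NX3;!$(NC=O);!$(N=O);!$(N[O-])]	expansion
nitrile	[NX1]#[CX2]	expansion
nitro	[NX3+](=O)[O-]	expansion
imine	[CX3]=[NX2]	expansion
oxime	[CX3]=[NX2][OX2H]	expansion
azo	[#6][NX2]=[NX2][#6]	expansion
hydrazine	[NX3][NX3]	expansion
carbamate	[NX3][CX3](=O)[OX2]	expansion
urea	[NX3][CX3](=O)[NX3]	expansion
thiol	[#6][SX2H]	expansion
thioether	[#6][SX2]([#6])	expansion
disulfide	[SX2][SX2]	expansion
sulfoxide	[SX3](=O)([#6])[#6]	expansion
sulfone	[SX4](=O)(=O)([#6])[#6]	expansion
sulfonamide	[SX4](=O)(=O)[NX3]	expansion
phosphate ester	[OX2][PX4](=O)([OX2])[OX2]	expansion
phosphorothioate	[PX4](=S)([OX2])([OX2])[OX2]	expansion
halide	[#6][F,Cl,Br,I]	expansion
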