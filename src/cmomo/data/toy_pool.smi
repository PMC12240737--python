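# Toy molecule pool for the packaged test world: drug-like molecules plus
# deliberate constraint violators (3-, 4- and 7-membered rings; molecules
# bearing packaged structural alerts). One SMILES per line.
CC(=O)Oc1ccccc1C(=O)O	aspirin
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine
CC(C)Cc1ccc(cc1)C(C)C(=O)O	ibuprofen
CC(=O)Nc1ccc(O)cc1	acetaminophen
Clc1ccccc1-c1nnc(o1)N1CCN(C)CC1
c1ccc2c(c1)oc(=O)c(c2)CC(=O)O
OCC(O)c1ccc(O)c(O)c1
CN1CCC[C@H]1c1cccnc1	nicotine
CC(N)Cc1ccccc1	amphetamine
NCCc1ccc(O)c(O)c1	dopamine
OC(=O)c1ccccc1O	salicylic_acid
Nc1ccc(cc1)S(=O)(=O)N	sulfanilamide
CCOC(=O)c1ccccc1N	benzocaine
COc1ccc2cc(ccc2c1)C(C)C(=O)O	naproxen
CN(C)CCCN1c2ccccc2Sc2ccccc21	promazine
Oc1ccc(cc1)C(c1ccc(O)cc1)C
NC(=O)c1ccc(cc1)N1CCOCC1
CC(C)NCC(O)COc1ccccc1
c1ccc(cc1)C(=O)NC1CCCCC1
CC1CCN(CC1)C(=O)c1ccco1
Cc1ccc(cc1)S(=O)(=O)Nc1ccccc1
COc1cc2c(cc1OC)CCN(C)C2
Oc1ccc2CCCNC(=O)c2c1
Fc1ccc(cc1)C(=O)N1CCN(C)CC1
Cc1onc(c1C(=O)N)c1ccccc1
Nc1ncnc2n(cnc12)C1OC(CO)C(O)C1O	adenosine
OC(=O)CCc1ccc(O)cc1
c1ccc(cc1)N1CCN(CC1)c1ncccn1
COc1ccccc1OCC(O)CN1CCCCC1
CCN(CC)C(=O)c1ccccc1N
Clc1cccc(c1)N1CCN(CCO)CC1
Cc1ncc(n1CCO)[N+](=O)[O-]	metronidazole
O=C(O)c1cc(ccc1O)C=O
ClCCN(C)CCCl	mechlorethamine
C1CC1c1ccccc1	cyclopropylbenzene
C1CCC1c1ccc(O)cc1	cyclobutylphenol
C1CCCCCC1	cycloheptane
OC1CCCCCC1	cycloheptanol
O=C1CCCCC1	cyclohexanone
c1ccc2c(c1)cccn2	quinoline
Cc1cccc(C)c1NC(=O)CN(CC)CC	lidocaine
CN1CCN(CC1)c1ccc(OC)cc1
COC(=O)c1ccccc1O	methyl_salicylate
OCc1ccccc1	benzyl_alcohol
NCCc1c[nH]c2ccccc12	tryptamine
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1	salbutamol
CN1C2CCC1CC(C2)OC(=O)C(CO)c1ccccc1	atropine
CCC(=O)Nc1ccc(cc1)N(CC)CC
Oc1ccc(Cl)cc1Cc1cc(Cl)ccc1O	dichlorophene
Cc1ccccc1NC(=O)c1ccccc1N
CC(C)(C)c1ccc(cc1)C(O)CCCN1CCC(CC1)C(O)(c1ccccc1)c1ccccc1	terfenadine
CN(C)CCOC(c1ccccc1)c1ccccc1	diphenhydramine
CCOc1ccccc1C(=O)NCC1CCCN1C
O=c1[nH]c(=O)c2[nH]cnc2[nH]1	xanthine
Cn1cc(c(=O)c2cc(F)c(cc12)N1CCNCC1)C(=O)O	norfloxacin_like
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O	penicillin_g
CC(O)C(=O)O	lactic_acid
CC(C)CC(N)C(=O)O	leucine
NC(Cc1ccccc1)C(=O)O	phenylalanine
NC(CO)C(=O)O	serine
NC(CS)C(=O)O	cysteine
OC(=O)C1CCCN1	proline
CC(=O)NCCc1c[nH]c2ccc(OC)cc12	melatonin
CN1CCCC1=O	methylpyrrolidone
O=C1NC(=O)NC(=O)C1(CC)c1ccccc1	phenobarbital_like
CCCCC1(CC)C(=O)NC(=O)NC1=O
Nc1ccc(cc1)C(=O)O	PABA
Oc1ccccc1C(=O)Nc1ccccc1	salicylanilide
CN(C)c1ccc(cc1)C=O
Oc1ccc(C=O)cc1OC	vanillin
O=[N+]([O-])c1ccc(cc1)C(=O)O	nitrobenzoic_acid
Nc1ccc(cc1)[N+](=O)[O-]	nitroaniline
CSc1ccccc1N
SCc1ccccc1	benzyl_mercaptan
OOC(C)(C)c1ccccc1	cumene_hydroperoxide
C1OC1COc1ccccc1	phenyl_glycidyl_ether
ClCC(=O)c1ccccc1	chloroacetophenone
N=Nc1ccccc1
CCOC(=O)CBr	ethyl_bromoacetate
CC(=O)OOC(C)=O	acetyl_peroxide
O=C1C=CC(=O)C=C1	benzoquinone
[Si](C)(C)(C)c1ccccc1	trimethylphenylsilane
O=C(Cl)c1ccccc1	benzoyl_chloride
CCN(CC)CCNC(=O)c1ccc(N)cc1	procainamide
COc1ccc(CCN(C)C)cc1
Cc1cc(C)nc(NS(=O)(=O)c2ccc(N)cc2)n1	sulfamethazine_like
Oc1ccc(CC2NCCc3cc(O)c(O)cc23)cc1
CC(C)(C)NCC(O)COc1cccc2[nH]ccc12	pindolol_like
CN1CCc2cccc3c2C1Cc1ccc(O)c(O)c1-3	apomorphine_like
CC(C)NCC(O)COc1ccc(COCCOC(C)C)cc1	bisoprolol_like
CCc1ccccc1O
CCCCc1ccccc1
Oc1ccc(cc1)S(=O)(=O)c1ccc(O)cc1
CC(C)Oc1ccccc1C(=O)N
CN(C)CCc1c[nH]c2ccc(CS(=O)(=O)N)cc12	sumatriptan
COc1ccc(cc1)C(=O)CCN1CCC(O)CC1
Fc1ccc(cc1)C(O)CN1CCC(CC1)Cc1ccccc1
Clc1ccc(cc1)C(=O)NCCN1CCOCC1
Cc1ccc(cc1)C(=O)c1ccc(CC(C)C(=O)O)cc1
OCC1OC(O)C(O)C(O)C1O	glucose_like
CC(=O)c1ccc(OC)cc1
c1csc(c1)C(=O)N1CCCC1
Cn1cnc(c1)C(=O)NCCO
OC(c1ccccc1)c1ccccc1	benzhydrol
CCOC(=O)N1CCN(CC1)c1ccccc1
Cc1cc2c(cc1C)N(C)C(=O)CN2
CC1CC(C)C(=O)C(C1)C1CCCCN1	lobeline_like
Oc1cccc2c1C(=O)c1ccccc1C2=O	anthraquinone_deriv
NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O	hydrochlorothiazide
CC(CN1CCCCC1)c1ccccc1
C1CN(CCN1)c1ccc(F)cc1
COc1cc(CC=C)ccc1O	eugenol
C(CC1CCCCN1)c1ccncc1
CC12CCC(CC1)C(C)(C)O2	eucalyptol_like
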