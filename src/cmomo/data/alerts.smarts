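# Structural alerts: common reactive, toxic, or uncommon substructures used
# as the packaged default for the substructure constraint. One SMARTS per
# line, tab-separated label. This is a curated subset of widely recognized
# medicinal-chemistry alert motifs; replace with a task-specific list
# (e.g. a full published screening deck) via the alerts config field.
[N+](=O)[O-]	nitro_group
[CX3H1](=O)[#6]	aldehyde
C(=O)Cl	acyl_chloride
C(=O)Br	acyl_bromide
[SX2H]	thiol
N=[N+]=[N-]	azide
N=N	azo
[NX3][NX3]	hydrazine
C=[N+]=[N-]	diazo
N=C=O	isocyanate
N=C=S	isothiocyanate
C1OC1	epoxide
C1NC1	aziridine
[OX2][OX2]	peroxide
C(=O)O[CH3,CH2]C(=O)	acylating_diester
[CX4][Cl,Br,I]	alkyl_halide_heavy
S(=O)(=O)[Cl,Br]	sulfonyl_halide
[CH]=[CH][CH]=[CH][CH]=[CH]	extended_polyene
C=C-C#N	acrylonitrile_michael_acceptor
C=CC(=O)[!N!O;!$([O-])]	vinyl_ketone
O=C1C=CC(=O)C=C1	quinone
[C;!R](=[N;!R])[N;!R]	acyclic_amidine
[N;R0]=[C;R0][N;R0]	open_chain_formamidine
C(=S)N	thioamide
P(=O)(O)(O)O	phosphate_monoester
[Si]	silicon
[Se]	selenium
[B;!$(B(O)O)]	boron_nonboronic
[I;$(I[c,C])]	aryl_or_alkyl_iodide
[N+]#[C-]	isonitrile
O=C-O-C=O	anhydride
[SX4](=O)(=O)F	sulfonyl_fluoride
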