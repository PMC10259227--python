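# Interfacial solvation free-energy scale (dG water -> POPC interface,
# kcal/mol) per amino acid, transcribed from Wimley & White (1996),
# Nat. Struct. Biol. 3:842-848 (charged forms for Asp/Glu/Lys/Arg, neutral
# His).  Lower (more negative) = partitions more favourably out of water.
# residue<TAB>score
ALA	0.17
ARG	0.81
ASN	0.42
ASP	1.23
CYS	-0.24
GLN	0.58
GLU	2.02
GLY	0.01
HIS	0.17
ILE	-0.31
LEU	-0.56
LYS	0.99
MET	-0.23
PHE	-1.13
PRO	0.45
SER	0.13
THR	0.14
TRP	-1.85
TYR	-0.94
VAL	0.07
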