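# Heavy atoms per standard residue EXCLUDING the peptide-bond backbone atoms
# N, C, O.  CA and all side-chain heavy atoms are counted.  Used to decompose
# per-residue scale scores into per-atom scores.
# residue<TAB>count
ALA	2
ARG	8
ASN	5
ASP	5
CYS	3
GLN	6
GLU	6
GLY	1
HIS	7
ILE	5
LEU	5
LYS	6
MET	5
PHE	8
PRO	4
SER	3
THR	4
TRP	11
TYR	9
VAL	4
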