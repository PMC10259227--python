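# 12-6 Lennard-Jones parameters for the united-atom methyl (-CH3) probe and
# for protein heavy-atom elements, GRID/Goodford-style empirical nonbonded
# values.  epsilon in kcal/mol; rmin_half in Å (r_min of a pair is the sum of
# the two rmin_half values, Lorentz combination; epsilon_ij is the geometric
# mean).  The PROBE row is the methyl probe itself.
# atom<TAB>epsilon<TAB>rmin_half
PROBE	0.160	2.17
C	0.105	2.00
N	0.170	1.85
O	0.210	1.70
S	0.250	2.00
P	0.200	2.10
SE	0.290	2.10
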