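# Van der Waals radii (Å), Bondi (1964) values for the elements found in
# protein heavy atoms.  Used for atomic-contact-pair demarcation.
# element<TAB>radius_angstrom
C	1.70
N	1.55
O	1.52
S	1.80
P	1.80
SE	1.90
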