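# Default functional-region definitions for the CRP homodimer
# (author residue numbering; chains A and B are the two subunits).
#
# hinge       - inter-domain hinge L134-D138
# camp_site   - cAMP-domain flexible site K52-E58
# dna_site    - DNA-domain site G173-V176
# dna_flex    - DNA-domain flexible site P154-A156
# dna_domain  - DNA-binding domain V139-R209
# camp_domain - cAMP-binding domain V1-N133

hinge_A = A:134-138
camp_site_A = A:52-58
dna_site_A = A:173-176
dna_flex_A = A:154-156
dna_domain_A = A:139-209
camp_domain_A = A:1-133

hinge_B = B:134-138
camp_site_B = B:52-58
dna_site_B = B:173-176
dna_flex_B = B:154-156
dna_domain_B = B:139-209
camp_domain_B = B:1-133
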