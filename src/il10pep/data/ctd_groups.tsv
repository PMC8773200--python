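# Three-group partitions of the 20-letter amino-acid alphabet used by the
# composition/transition/distribution (CTD) descriptors.
# After Dubchak I. et al. (1995) PNAS 92:8700-8704, as standardized by the
# PROFEAT/iFeature descriptor platforms. Each attribute splits the alphabet
# into three disjoint, exhaustive classes (group1/group2/group3).
attribute	group1	group2	group3
hydrophobicity	RKEDQN	GASTPHY	CLVIMFW
vdw_volume	GASTPDC	NVEQIL	MHKFRYW
polarity	LIFWCMVY	PATGS	HQRKNED
polarizability	GASDT	CPNVEQIL	KMHFRYW
charge	KR	ANCQGHILMFPSTWYV	DE
secondary_structure	EALMQKRH	VIYCWFT	GNPSD
solvent_accessibility	ALFCGIVW	RKQEND	MSPTHY
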