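# Per-residue physicochemical scales backing the autocorrelation descriptors.
# One column per property, one row per residue. Values are z-scored over the
# 20-letter alphabet before use.
# Sources:
#   hydrophobicity  - Kyte J., Doolittle R.F. (1982) J Mol Biol 157:105-132
#   flexibility     - Bhaskaran R., Ponnuswamy P.K. (1988) Int J Pept Protein Res 32:241-255
#   polarizability  - Charton M., Charton B.I. (1982) J Theor Biol 99:629-644
#   free_energy     - Charton M., Charton B.I. (1982) J Theor Biol 99:629-644 (solution in water, kcal/mol)
#   asa             - Chothia C. (1976) J Mol Biol 105:1-12 (accessible surface area, A^2)
#   volume          - Bigelow C.C. (1967) J Theor Biol 16:187-211 (residue volume, A^3)
#   steric          - Charton M. (1981) J Theor Biol 91:115-134 (steric parameter)
#   mutability      - Dayhoff M.O. et al. (1978) Atlas of Protein Sequence and Structure (relative mutability)
aa	hydrophobicity	flexibility	polarizability	free_energy	asa	volume	steric	mutability
A	1.8	0.357	0.046	-0.368	115.0	52.6	0.52	100.0
C	2.5	0.346	0.128	4.530	135.0	68.3	0.62	20.0
D	-3.5	0.511	0.105	2.060	150.0	68.4	0.76	106.0
E	-3.5	0.497	0.151	1.770	190.0	84.7	0.68	102.0
F	2.8	0.314	0.290	1.060	210.0	113.9	0.70	41.0
G	-0.4	0.544	0.000	-0.525	75.0	36.3	0.00	49.0
H	-3.2	0.323	0.230	0.000	195.0	91.9	0.70	66.0
I	4.5	0.462	0.186	0.791	175.0	102.0	1.02	96.0
K	-3.9	0.466	0.219	0.000	200.0	105.1	0.68	56.0
L	3.8	0.365	0.186	1.070	170.0	102.0	0.98	40.0
M	1.9	0.295	0.221	0.656	185.0	97.7	0.78	94.0
N	-3.5	0.463	0.134	0.000	160.0	75.7	0.76	134.0
P	-1.6	0.509	0.131	-2.240	145.0	73.6	0.36	56.0
Q	-3.5	0.493	0.180	0.731	180.0	89.7	0.68	93.0
R	-4.5	0.529	0.291	-1.030	225.0	109.1	0.68	65.0
S	-0.8	0.507	0.062	-0.524	115.0	54.9	0.53	120.0
T	-0.7	0.444	0.108	0.000	140.0	71.2	0.50	97.0
V	4.2	0.386	0.140	0.401	155.0	85.1	0.76	74.0
W	-0.9	0.305	0.409	1.600	255.0	135.4	0.70	18.0
Y	-1.3	0.420	0.298	4.910	230.0	116.2	0.70	41.0
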