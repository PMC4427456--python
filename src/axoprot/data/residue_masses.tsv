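# Standard residue (monomer) masses for the 20 proteinogenic amino acids.
# Columns: one-letter code, monoisotopic mass (Da), average mass (Da).
# Residue mass = amino acid mass minus one water (the polymerised unit).
G	57.02146	57.0519
A	71.03711	71.0788
S	87.03203	87.0782
P	97.05276	97.1167
V	99.06841	99.1326
T	101.04768	101.1051
C	103.00919	103.1388
L	113.08406	113.1594
I	113.08406	113.1594
N	114.04293	114.1038
D	115.02694	115.0886
Q	128.05858	128.1307
K	128.09496	128.1741
E	129.04259	129.1155
M	131.04049	131.1926
H	137.05891	137.1411
F	147.06841	147.1766
R	156.10111	156.1875
Y	163.06333	163.1760
W	186.07931	186.2132
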