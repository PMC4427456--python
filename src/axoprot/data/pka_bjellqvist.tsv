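# Bjellqvist pKa set for polypeptide isoelectric-point prediction
# (the de facto standard for 2DE first-dimension position estimates).
# Columns: group, pKa (pH units), charge sign at low pH occupancy.
# "nterm"/"cterm" are the free termini; single letters are side chains.
nterm	7.50	+1
cterm	3.55	-1
D	4.05	-1
E	4.45	-1
C	9.00	-1
Y	10.00	-1
H	5.98	+1
K	10.00	+1
R	12.00	+1
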