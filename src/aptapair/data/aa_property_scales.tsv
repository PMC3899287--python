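# Five physicochemical summary scales for the 20 standard amino acids:
# the factor scores of Atchley, Zhao, Fernandes & Druke (2005),
# "Solving the protein sequence metric problem", PNAS 102:6395-6400, Table 2.
# Column mapping: polarity = factor I (polarity/accessibility/hydrophobicity),
# codon_diversity = factor IV, electrostatic_charge = factor V,
# molecular_volume = factor III (molecular size/volume),
# secondary_structure = factor II (propensity for secondary structure).
# Scales are re-standardized to mean 0 / SD 1 over the 20 residues at load
# time, so only relative spacing matters here.
amino_acid	polarity	codon_diversity	electrostatic_charge	molecular_volume	secondary_structure
A	-0.591	1.570	-0.146	-0.733	-1.302
C	-1.343	-1.020	-0.255	-0.862	0.465
D	1.050	-0.259	-3.242	-3.656	0.302
E	1.357	0.113	-0.837	1.477	-1.453
F	-1.006	-0.397	0.412	1.891	-0.590
G	-0.384	1.045	2.064	1.330	1.652
H	0.336	-1.474	-0.078	-1.673	-0.417
I	-1.239	0.393	0.816	2.131	-0.547
K	1.831	-0.277	1.648	0.533	-0.561
L	-1.019	1.266	-0.912	-1.505	-0.987
M	-0.663	-1.005	1.212	2.219	-1.524
N	0.945	-0.169	0.933	1.299	0.828
P	0.189	0.421	-1.392	-1.628	2.081
Q	0.931	-0.503	-1.853	-3.005	-0.179
R	1.538	0.440	2.897	1.502	-0.055
S	-0.228	0.670	-2.647	-4.760	1.399
T	-0.032	0.908	1.313	2.213	0.326
V	-1.337	1.242	-1.262	-0.544	-0.279
W	-0.595	-2.128	-0.184	0.672	0.009
Y	0.260	-0.838	1.512	3.097	0.830
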