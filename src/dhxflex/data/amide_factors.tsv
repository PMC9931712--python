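# Side-chain inductive factors for backbone amide exchange, log10 scale,
# poly-DL-alanine reference (Bai et al., Proteins 17:75-86, 1993).
# lambda: effect of a residue's side chain on its own amide.
# rho:    effect of a residue's side chain on the following residue's amide.
# D0/E0/H0 are the protonated (COOH / imidazolium) forms; D/E/H deprotonated.
# C = reduced cysteine, C2 = cystine. Proline has no amide H (lambda unused).
# version: 1
res	acid_lambda	acid_rho	base_lambda	base_rho
A	0.00	0.00	0.00	0.00
C	-0.54	-0.46	0.62	0.55
C2	-0.74	-0.58	0.55	0.46
D	0.90	0.58	0.10	-0.18
D0	-0.90	-0.12	0.69	0.60
E	-0.90	-0.31	-0.11	-0.15
E0	-0.60	-0.27	0.24	0.39
F	-0.52	-0.43	-0.24	0.06
G	-0.22	0.22	0.27	0.17
H	0.00	0.00	-0.10	0.14
H0	-0.80	-0.51	0.80	0.83
I	-0.91	-0.59	-0.59	-0.32
K	-0.56	-0.29	-0.04	0.12
L	-0.57	-0.13	-0.13	0.11
M	-0.64	-0.28	-0.01	0.11
N	-0.58	-0.13	0.49	0.32
P	0.00	-0.19	0.00	-0.24
Q	-0.47	-0.27	0.06	0.20
R	-0.59	-0.32	0.08	0.22
S	-0.44	-0.39	0.37	0.30
T	-0.79	-0.47	-0.07	-0.28
V	-0.74	-0.30	-0.30	-0.14
W	-0.40	-0.44	-0.41	-0.11
Y	-0.41	-0.37	-0.27	0.05
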