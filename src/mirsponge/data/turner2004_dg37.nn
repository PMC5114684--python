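# Turner 2004 RNA-RNA nearest-neighbour free energies, dG37 (kcal/mol).
# Watson-Crick stacks at the published 0.01 kcal/mol precision (Xia et al. 1998);
# wobble-containing stacks and loop initiations at 0.1 kcal/mol (Mathews et al. 2004).
# STACKS key: 5'XY3'/3'ZW5' -- X pairs Z, Y pairs W; table is 180-degree symmetric.
[STACKS]
AA/UU   -0.93
AC/UG   -2.24
AG/UC   -2.08
AG/UU   -0.60
AU/UA   -1.10
AU/UG   -1.40
CA/GU   -2.11
CC/GG   -3.26
CG/GC   -2.36
CG/GU   -1.40
CU/GA   -2.08
CU/GG   -2.10
GA/CU   -2.35
GA/UU   -1.30
GC/CG   -3.42
GC/UG   -2.50
GG/CC   -3.26
GG/CU   -1.50
GG/UC   -2.10
GG/UU   -0.50
GU/CA   -2.24
GU/CG   -2.50
GU/UA   -1.40
GU/UG    1.30
UA/AU   -1.33
UA/GU   -1.00
UC/AG   -2.35
UC/GG   -1.50
UG/AC   -2.11
UG/AU   -1.00
UG/GC   -1.40
UG/GU    0.30
UU/AA   -0.93
UU/AG   -1.30
UU/GA   -0.60
UU/GG   -0.50

# Bulge-loop initiation by loop size (nt); sizes beyond 30 are extrapolated
# with the Jacobson-Stockmayer term dG(n) = dG(30) + lxc*ln(n/30).
[BULGE]
 1   3.80
 2   2.80
 3   3.20
 4   3.60
 5   4.00
 6   4.40
 7   4.60
 8   4.70
 9   4.80
10   4.90
11   5.00
12   5.10
13   5.20
14   5.30
15   5.40
16   5.40
17   5.50
18   5.50
19   5.60
20   5.70
21   5.70
22   5.80
23   5.80
24   5.80
25   5.90
26   5.90
27   6.00
28   6.00
29   6.00
30   6.10

# Internal-loop initiation by total loop size (nt, both strands summed).
[INTERNAL]
 2   1.00
 3   1.00
 4   1.10
 5   2.00
 6   2.00
 7   2.10
 8   2.30
 9   2.40
10   2.50
11   2.60
12   2.70
13   2.80
14   2.90
15   2.90
16   3.00
17   3.10
18   3.10
19   3.20
20   3.30
21   3.30
22   3.40
23   3.40
24   3.50
25   3.50
26   3.50
27   3.60
28   3.60
29   3.70
30   3.70

# helix_init: duplex initiation; au_end_penalty: per terminal AU/GU pair;
# ninio_coeff/ninio_max: internal-loop asymmetry penalty min(max, coeff*|n1-n2|);
# lxc = 1.75*R*T at 310.15 K, for loop-size extrapolation beyond the tables.
[MISC]
helix_init      4.09
au_end_penalty  0.45
ninio_coeff     0.60
ninio_max       3.00
lxc             1.07856
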