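# Position-dependent mismatch penalty weights for SpCas9 (20-nt guide).
# Transcribed from Hsu et al. 2013, Nat Biotechnol 31:827-832 (the
# 'MIT/Zhang-lab' specificity weight vector). Position 1 = PAM-distal end.
position	weight
1	0.0
2	0.0
3	0.014
4	0.0
5	0.0
6	0.395
7	0.317
8	0.0
9	0.389
10	0.079
11	0.445
12	0.508
13	0.613
14	0.851
15	0.732
16	0.828
17	0.615
18	0.804
19	0.685
20	0.583
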