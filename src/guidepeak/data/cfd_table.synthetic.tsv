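# SYNTHETIC substitution-factor table with the structure of a CFD-style
# model (per-position, per-substitution activity factors in [0,1];
# position 1 = PAM-distal end of a 20-nt guide). These numbers are a
# deterministic placeholder, NOT the published CFD values (Doench et al.
# 2016); supply the published table via the user-matrix interface for
# real predictions. PAM-proximal mismatches penalised more, transitions
# tolerated more than transversions.
position	guide_base	genome_base	factor
1	A	C	0.6
1	A	G	0.9
1	A	T	0.6
1	C	A	0.6
1	C	G	0.6
1	C	T	0.9
1	G	A	0.9
1	G	C	0.6
1	G	T	0.6
1	T	A	0.6
1	T	C	0.9
1	T	G	0.6
2	A	C	0.5763
2	A	G	0.8645
2	A	T	0.5763
2	C	A	0.5763
2	C	G	0.5763
2	C	T	0.8645
2	G	A	0.8645
2	G	C	0.5763
2	G	T	0.5763
2	T	A	0.5763
2	T	C	0.8645
2	T	G	0.5763
3	A	C	0.5526
3	A	G	0.8289
3	A	T	0.5526
3	C	A	0.5526
3	C	G	0.5526
3	C	T	0.8289
3	G	A	0.8289
3	G	C	0.5526
3	G	T	0.5526
3	T	A	0.5526
3	T	C	0.8289
3	T	G	0.5526
4	A	C	0.5289
4	A	G	0.7934
4	A	T	0.5289
4	C	A	0.5289
4	C	G	0.5289
4	C	T	0.7934
4	G	A	0.7934
4	G	C	0.5289
4	G	T	0.5289
4	T	A	0.5289
4	T	C	0.7934
4	T	G	0.5289
5	A	C	0.5053
5	A	G	0.7579
5	A	T	0.5053
5	C	A	0.5053
5	C	G	0.5053
5	C	T	0.7579
5	G	A	0.7579
5	G	C	0.5053
5	G	T	0.5053
5	T	A	0.5053
5	T	C	0.7579
5	T	G	0.5053
6	A	C	0.4816
6	A	G	0.7224
6	A	T	0.4816
6	C	A	0.4816
6	C	G	0.4816
6	C	T	0.7224
6	G	A	0.7224
6	G	C	0.4816
6	G	T	0.4816
6	T	A	0.4816
6	T	C	0.7224
6	T	G	0.4816
7	A	C	0.4579
7	A	G	0.6868
7	A	T	0.4579
7	C	A	0.4579
7	C	G	0.4579
7	C	T	0.6868
7	G	A	0.6868
7	G	C	0.4579
7	G	T	0.4579
7	T	A	0.4579
7	T	C	0.6868
7	T	G	0.4579
8	A	C	0.4342
8	A	G	0.6513
8	A	T	0.4342
8	C	A	0.4342
8	C	G	0.4342
8	C	T	0.6513
8	G	A	0.6513
8	G	C	0.4342
8	G	T	0.4342
8	T	A	0.4342
8	T	C	0.6513
8	T	G	0.4342
9	A	C	0.4105
9	A	G	0.6158
9	A	T	0.4105
9	C	A	0.4105
9	C	G	0.4105
9	C	T	0.6158
9	G	A	0.6158
9	G	C	0.4105
9	G	T	0.4105
9	T	A	0.4105
9	T	C	0.6158
9	T	G	0.4105
10	A	C	0.3868
10	A	G	0.5803
10	A	T	0.3868
10	C	A	0.3868
10	C	G	0.3868
10	C	T	0.5803
10	G	A	0.5803
10	G	C	0.3868
10	G	T	0.3868
10	T	A	0.3868
10	T	C	0.5803
10	T	G	0.3868
11	A	C	0.3632
11	A	G	0.5447
11	A	T	0.3632
11	C	A	0.3632
11	C	G	0.3632
11	C	T	0.5447
11	G	A	0.5447
11	G	C	0.3632
11	G	T	0.3632
11	T	A	0.3632
11	T	C	0.5447
11	T	G	0.3632
12	A	C	0.3395
12	A	G	0.5092
12	A	T	0.3395
12	C	A	0.3395
12	C	G	0.3395
12	C	T	0.5092
12	G	A	0.5092
12	G	C	0.3395
12	G	T	0.3395
12	T	A	0.3395
12	T	C	0.5092
12	T	G	0.3395
13	A	C	0.3158
13	A	G	0.4737
13	A	T	0.3158
13	C	A	0.3158
13	C	G	0.3158
13	C	T	0.4737
13	G	A	0.4737
13	G	C	0.3158
13	G	T	0.3158
13	T	A	0.3158
13	T	C	0.4737
13	T	G	0.3158
14	A	C	0.2921
14	A	G	0.4382
14	A	T	0.2921
14	C	A	0.2921
14	C	G	0.2921
14	C	T	0.4382
14	G	A	0.4382
14	G	C	0.2921
14	G	T	0.2921
14	T	A	0.2921
14	T	C	0.4382
14	T	G	0.2921
15	A	C	0.2684
15	A	G	0.4026
15	A	T	0.2684
15	C	A	0.2684
15	C	G	0.2684
15	C	T	0.4026
15	G	A	0.4026
15	G	C	0.2684
15	G	T	0.2684
15	T	A	0.2684
15	T	C	0.4026
15	T	G	0.2684
16	A	C	0.2447
16	A	G	0.3671
16	A	T	0.2447
16	C	A	0.2447
16	C	G	0.2447
16	C	T	0.3671
16	G	A	0.3671
16	G	C	0.2447
16	G	T	0.2447
16	T	A	0.2447
16	T	C	0.3671
16	T	G	0.2447
17	A	C	0.2211
17	A	G	0.3316
17	A	T	0.2211
17	C	A	0.2211
17	C	G	0.2211
17	C	T	0.3316
17	G	A	0.3316
17	G	C	0.2211
17	G	T	0.2211
17	T	A	0.2211
17	T	C	0.3316
17	T	G	0.2211
18	A	C	0.1974
18	A	G	0.2961
18	A	T	0.1974
18	C	A	0.1974
18	C	G	0.1974
18	C	T	0.2961
18	G	A	0.2961
18	G	C	0.1974
18	G	T	0.1974
18	T	A	0.1974
18	T	C	0.2961
18	T	G	0.1974
19	A	C	0.1737
19	A	G	0.2605
19	A	T	0.1737
19	C	A	0.1737
19	C	G	0.1737
19	C	T	0.2605
19	G	A	0.2605
19	G	C	0.1737
19	G	T	0.1737
19	T	A	0.1737
19	T	C	0.2605
19	T	G	0.1737
20	A	C	0.15
20	A	G	0.225
20	A	T	0.15
20	C	A	0.15
20	C	G	0.15
20	C	T	0.225
20	G	A	0.225
20	G	C	0.15
20	G	T	0.15
20	T	A	0.15
20	T	C	0.225
20	T	G	0.15
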