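chrom	genetic_cm	physical_mb	cm_per_mb
1	166.0	158.3	1.05
2	148.0	137.1	1.08
3	141.8	121.4	1.17
4	132.5	120.2	1.10
5	130.0	121.2	1.07
6	134.2	119.5	1.12
7	125.5	112.6	1.11
8	124.4	113.4	1.10
9	110.3	105.7	1.04
10	118.9	104.3	1.14
11	129.9	107.3	1.21
12	117.3	91.2	1.29
13	118.3	84.2	1.40
14	127.4	84.7	1.51
15	110.3	85.3	1.29
16	112.4	81.7	1.38
17	97.0	75.2	1.29
18	103.2	66.0	1.56
19	100.8	64.1	1.57
20	73.7	72.0	1.02
21	90.2	71.6	1.26
22	91.4	61.4	1.49
23	90.0	52.5	1.71
24	85.8	62.7	1.37
25	62.0	42.9	1.45
26	69.8	51.7	1.35
27	60.9	45.4	1.34
28	57.3	46.3	1.24
29	68.0	51.5	1.32
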