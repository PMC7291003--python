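# Published per-chromosome LD summary for a Piétrain PorcineSNP50 cohort (Sscrofa11.1):
# chromosome recombination rate (cM/Mb), mean r2 by physical distance bin (kb),
# and the LD-based Ne reported for the generation depth each bin maps to.
chrom	cm_per_mb	r2_100	r2_200	r2_500	r2_1000	r2_2000	r2_5000	ne_g500	ne_g250	ne_g100	ne_g50	ne_g25	ne_g10
1	0.5365	0.4472	0.3956	0.3188	0.2413	0.1666	0.0932	576.1	356.0	199.1	146.5	116.5	90.7
2	0.8691	0.4464	0.3976	0.3210	0.2474	0.1721	0.0977	356.8	218.0	121.7	87.5	69.2	53.1
3	0.9723	0.4486	0.4018	0.3248	0.2493	0.1752	0.1000	316.1	191.4	106.9	77.4	60.5	46.3
4	1.0000	0.4482	0.3980	0.3229	0.2488	0.1753	0.1004	307.8	189.1	104.8	75.5	58.8	44.8
5	1.4524	0.4518	0.4019	0.3264	0.2517	0.1766	0.1014	208.9	128.1	71.0	51.2	40.1	30.5
6	0.9690	0.4477	0.3960	0.3204	0.2457	0.1718	0.0989	318.3	196.7	109.4	79.2	62.2	47.0
7	1.2869	0.4495	0.4018	0.3253	0.2495	0.1749	0.1006	238.0	144.6	80.6	58.4	45.8	34.7
8	0.9403	0.4480	0.3999	0.3239	0.2475	0.1731	0.0991	327.7	199.5	111.0	80.9	63.5	48.3
9	0.9893	0.4462	0.3989	0.3238	0.2476	0.1747	0.1006	313.6	190.4	105.5	76.8	59.7	45.2
10	1.8551	0.4508	0.4012	0.3249	0.2490	0.1755	0.1010	164.2	100.6	56.0	40.6	31.7	24.0
11	1.0747	0.4504	0.4015	0.3248	0.2494	0.1746	0.0999	283.9	173.4	96.7	70.0	55.0	41.9
12	1.8242	0.4482	0.3994	0.3229	0.2486	0.1744	0.1006	168.7	103.1	57.5	41.4	32.4	24.5
13	0.6067	0.4505	0.4031	0.3255	0.2490	0.1742	0.0991	502.6	305.1	170.8	124.3	97.6	74.9
14	0.7331	0.4515	0.3999	0.3217	0.2465	0.1714	0.0982	414.3	255.9	143.8	104.2	82.4	62.6
15	0.9021	0.4470	0.4006	0.3242	0.2485	0.1747	0.1005	342.9	207.4	115.5	83.8	65.5	49.6
16	1.1650	0.4498	0.4015	0.3247	0.2503	0.1758	0.1003	262.5	160.0	89.3	64.3	50.3	38.5
17	1.5397	0.4488	0.3997	0.3234	0.2487	0.1740	0.0998	199.4	121.9	67.9	49.0	38.5	29.3
18	1.1859	0.4476	0.3980	0.3222	0.2476	0.1733	0.1003	260.1	159.5	88.7	64.1	50.3	37.8
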