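# LRET-derived inter-protomer distances (Å) for the Mre11-Rad50 complex,
# mean ± SD over >=3 replicates. One row per probe pair x construct x
# condition; the partially open state carries one value per acceptor
# channel (Bodipy FL and Cy3).
pair_a	pair_b	construct	condition	closed_mean	closed_sd	po_bodipy_mean	po_bodipy_sd	po_cy3_mean	po_cy3_sd	open_mean	open_sd
51	51	NBD	apo	37.5	0.7	46.2	1.3	46.1	1.7	81.4	2.2
51	51	NBD	ATP	37.7	0.6	45.4	1.1	47.0	1.0	78.0	2.0
51	51	NBD	ATPgS	37.9	0.1	47.7	0.4	48.0	0.5	79.1	1.1
51	51	NBD	ATP+hairpin	37.7	1.2	47.9	1.4	47.2	1.2	79.1	1.0
51	51	NBD	ATP+ssDNA	36.7	0.8	46.8	1.3	45.4	1.4	74.5	0.7
774	774	NBD	apo	33.7	0.6	56.0	0.3	50.6	1.5	85.0	1.2
774	774	NBD	ATP	35.7	0.2	51.5	2.3	45.8	1.8	83.5	2.2
774	774	NBD	ATPgS	35.6	0.1	53.0	1.5	48.6	0.2	82.6	3.0
774	774	NBD	ATP+hairpin	35.4	0.3	53.6	0.5	46.9	1.3	82.7	2.0
774	774	NBD	ATP+ssDNA	35.1	0.5	52.8	0.4	50.0	2.7	75.3	0.6
13	13	NBD	apo	36.7	1.0	55.6	0.3	46.0	0.9	79.9	2.2
13	13	NBD	ATP	35.4	0.3	51.1	1.0	50.9	1.1	77.8	1.7
13	13	NBD	ATPgS	37.1	0.1	51.9	0.1	47.0	1.2	77.1	0.2
13	13	NBD	ATP+hairpin	34.4	1.2	54.9	0.8	47.8	0.7	74.9	0.2
13	13	NBD	ATP+ssDNA	34.2	0.7	53.9	0.7	48.0	1.7	75.0	0.8
13	51	NBD	apo	34.7	0.1	55.4	1.0	50.1	0.8	84.1	1.6
13	51	NBD	ATP	36.7	1.1	51.4	0.9	51.6	0.3	79.7	3.0
13	51	NBD	ATPgS	36.0	0.2	52.8	0.2	51.3	0.2	79.7	1.1
13	51	NBD	ATP+hairpin	34.7	0.7	52.3	0.4	50.9	0.1	77.2	0.5
13	51	NBD	ATP+ssDNA	35.1	0.8	50.0	0.5	51.1	0.4	74.5	0.7
774	51	NBD	apo	33.0	0.8	53.0	0.8	48.9	1.8	84.0	0.9
774	51	NBD	ATP	30.9	0.2	51.5	0.4	49.6	1.5	80.8	1.9
774	51	NBD	ATPgS	31.2	0.3	49.6	0.6	47.6	0.9	77.8	0.2
774	51	NBD	ATP+hairpin	30.6	0.3	49.9	0.9	51.1	3.0	80.9	0.9
774	51	NBD	ATP+ssDNA	30.4	0.4	49.6	0.6	50.7	2.1	75.9	1.2
51	51	FL	apo	35.4	1.8	48.7	0.8	46.7	0.6	75.7	1.2
51	51	FL	ATP	37.3	0.1	49.6	0.2	46.3	0.1	74.7	0.5
51	51	FL	ATPgS	35.3	0.9	48.7	0.5	46.7	0.4	74.4	1.6
51	51	FL	ATP+hairpin	34.8	1.1	47.7	0.3	45.5	0.4	72.6	1.1
51	51	FL	ATP+ssDNA	34.9	1.1	47.2	0.4	45.5	0.6	71.0	0.5
774	774	FL	apo	32.8	0.6	46.8	0.6	48.3	0.8	89.0	3.1
774	774	FL	ATP	35.6	0.3	50.8	0.7	50.5	0.4	87.8	0.7
774	774	FL	ATPgS	33.8	0.3	46.7	0.2	50.1	0.4	86.0	1.5
774	774	FL	ATP+hairpin	33.6	0.3	45.5	0.6	46.7	1.8	79.9	1.8
774	774	FL	ATP+ssDNA	33.6	0.2	45.5	0.5	46.7	1.5	75.7	0.8
13	13	FL	apo	36.8	0.3	51.0	1.0	49.6	0.4	77.9	0.6
13	13	FL	ATP	36.4	0.3	50.9	0.2	50.7	0.2	79.4	0.1
13	13	FL	ATPgS	35.8	0.3	50.8	0.2	48.6	0.7	76.3	1.0
13	13	FL	ATP+hairpin	36.4	0.6	51.0	0.6	50.4	0.7	75.1	2.1
13	13	FL	ATP+ssDNA	36.9	0.7	51.3	1.0	49.7	0.2	75.1	0.2
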