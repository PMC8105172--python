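# Published protein-level confusion matrices and metrics for the
# fully-disordered-protein challenge (646 targets, 45 annotated IDPs at the
# >=95% disorder criterion). Baselines are marked in the baseline column.
# Used as exact test vectors for the point-metric conventions.
method	baseline	tn	fp	fn	tp	mcc	f1	tnr	tpr	ppv	bac
fIDPnn	0	585	16	19	26	0.569	0.598	0.973	0.578	0.619	0.776
RawMSA	0	582	19	19	26	0.546	0.578	0.968	0.578	0.578	0.773
VSL2B	0	578	23	22	23	0.468	0.505	0.962	0.511	0.500	0.736
fIDPlr	0	566	35	18	27	0.468	0.505	0.942	0.600	0.435	0.771
Predisorder	0	589	12	26	19	0.479	0.500	0.980	0.422	0.613	0.701
SPOT-Disorder1	0	572	29	23	22	0.416	0.458	0.952	0.489	0.431	0.720
DisoMine	0	551	50	17	28	0.421	0.455	0.917	0.622	0.359	0.770
AUCpreD	0	588	13	28	17	0.431	0.453	0.978	0.378	0.567	0.678
SPOT-Disorder2	0	574	27	24	21	0.409	0.452	0.955	0.467	0.438	0.711
SPOT-Disorder-Single	0	594	7	30	15	0.452	0.448	0.988	0.333	0.682	0.661
IsUnstruct	0	588	13	29	16	0.411	0.432	0.978	0.356	0.552	0.667
IUPred2A-long	0	595	6	32	13	0.420	0.406	0.990	0.289	0.684	0.639
Gene3D	1	505	96	10	35	0.391	0.398	0.840	0.778	0.267	0.809
ESpritz-N	0	597	4	33	12	0.426	0.393	0.993	0.267	0.750	0.630
ESpritz-D	0	555	46	23	22	0.342	0.389	0.923	0.489	0.324	0.706
PyHCA	0	596	5	33	12	0.411	0.387	0.992	0.267	0.706	0.629
JRONN	0	595	6	33	12	0.397	0.381	0.990	0.267	0.667	0.628
MobiDB-lite	0	599	2	34	11	0.437	0.379	0.997	0.244	0.846	0.621
DisPredict-2	0	586	15	32	13	0.330	0.356	0.975	0.289	0.464	0.632
IUPred2A-short	0	599	2	35	10	0.413	0.351	0.997	0.222	0.833	0.609
S2D-2	0	572	29	30	15	0.288	0.337	0.952	0.333	0.341	0.643
PDB Observed	1	468	133	13	32	0.286	0.305	0.779	0.711	0.194	0.745
AUCpreD-np	0	590	11	35	10	0.293	0.303	0.982	0.222	0.476	0.602
ESpritz-X	0	595	6	36	9	0.321	0.300	0.990	0.200	0.600	0.595
FoldUnfold	0	456	145	14	31	0.256	0.281	0.759	0.689	0.176	0.724
DISOPRED-3.1	0	596	5	39	6	0.246	0.214	0.992	0.133	0.545	0.563
DisEMBL-HL	0	601	0	41	4	0.288	0.163	1.000	0.089	1.000	0.544
PDB Remote	1	590	11	42	3	0.085	0.102	0.982	0.067	0.214	0.524
DisEMBL-465	0	601	0	43	2	0.204	0.085	1.000	0.044	1.000	0.522
PDB Close	1	589	12	43	2	0.043	0.068	0.980	0.044	0.143	0.512
Conservation	1	441	160	38	7	-0.064	0.066	0.734	0.156	0.042	0.445
DynaMine	0	601	0	45	0	0.000	0.000	1.000	0.000	0.000	0.500
GlobPlot	0	601	0	45	0	0.000	0.000	1.000	0.000	0.000	0.500
DFLpred	0	601	0	45	0	0.000	0.000	1.000	0.000	0.000	0.500
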