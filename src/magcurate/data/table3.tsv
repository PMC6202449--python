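strain	preset	bin_id	taxon	nature	n_scaffolds	length_pct	coverage_med	completeness	contamination	strain_heterogeneity
ULC335	veryspecific	bin1	Cyanobacteria	C	238	20.84	10.90	98.91	0.51	na
ULC335	veryspecific	bin2	Flavobacteriaceae	M	67	13.73	11.12	99.29	0.12	na
ULC335	veryspecific	bin3	Bacteroidetes	M	576	12.83	4.46	65.45	0.49	na
ULC335	veryspecific	bin4	Alphaproteobacteria	M	271	4.79	4.13	32.28	0	na
ULC335	veryspecific	nobin	Nobin	No	23056	47.81	1.88	na	na	na
ULC007	superspecific	bin1	Cyanobacteria	C	84	91.14	26.62	98.11	0	na
ULC007	superspecific	bin2	Unclassified	U	12	4.95	72.12	0	0	na
ULC007	superspecific	nobin	Nobin	No	358	3.91	1.48	na	na	na
ULC027	verysensitive	bin1	Cyanobacteria	C	439	21.40	6.27	90.43	0.27	na
ULC027	verysensitive	bin2	Alphaproteobacteria	M	190	16.16	7.71	95.02	1.16	na
ULC027	verysensitive	bin3	Sphingomonadales	M	293	12.03	6.18	60.21	2.35	na
ULC027	verysensitive	bin4	Unclassified	U	164	4.16	5.09	4.17	0	na
ULC027	verysensitive	nobin	Nobin	No	24364	46.24	1.89	na	na	na
ULC041	verysensitive	bin1	Cyanobacteria	C	287	84.76	31.38	96.2	1.63	na
ULC041	verysensitive	bin2	Unclassified	U	24	9.36	44.33	0	0	na
ULC041	verysensitive	nobin	Nobin	No	441	5.88	3.97	na	na	na
ULC065	veryspecific	bin1	Cyanobacteria	C	95	22.36	38.37	99.09	0.27	na
ULC065	veryspecific	bin2	Xanthomonadaceae	M	332	19.33	6.19	83.73	1.23	na
ULC065	veryspecific	nobin	Nobin	No	20555	58.31	1.73	na	na	na
ULC066	superspecific	bin1	Cyanobacteria	C	67	28.81	21.86	98.82	0.47	na
ULC066	superspecific	bin2	Bacteroidetes	M	401	13.94	4.93	76.91	1.23	na
ULC066	superspecific	bin3	Betaproteobacteria	M	152	2.86	3.48	15.86	0	na
ULC066	superspecific	nobin	Nobin	No	24558	54.38	1.69	na	na	na
ULC068	superspecific	bin1	Cyanobacteria	C	60	57.04	29.34	97.09	0.71	na
ULC068	superspecific	bin2	Unclassified	U	3	2.56	22.60	0	0	na
ULC068	superspecific	nobin	Nobin	No	10385	40.41	1.42	na	na	na
ULC073	verysensitive	bin1	Cyanobacteria	C	476	22.70	10.74	92.03	1.42	na
ULC073	verysensitive	bin2	Betaproteobacteria	M	65	16.26	7.99	97.92	0.67	na
ULC073	verysensitive	bin3	Sphingomonadales	M	603	15.78	4.94	70.57	5.3	na
ULC073	verysensitive	bin4	Bacteria	M	156	2.79	4.39	10.71	0	na
ULC073	verysensitive	bin5	Unclassified	U	26	1.40	15.02	0	0	na
ULC073	verysensitive	bin6	Unclassified	U	29	1.38	6.45	0	0	na
ULC073	verysensitive	nobin	Nobin	No	16790	39.68	1.94	na	na	na
ULC077	veryspecific	bin1	Cyanobacteria	C	407	47.37	15.08	97.64	0.47	na
ULC077	veryspecific	nobin	Nobin	No	14903	52.63	1.83	na	na	na
ULC082	veryspecific	bin1	Cyanobacteria	C	124	11.49	19.85	97.74	0.27	na
ULC082	veryspecific	bin2	Bacteria	M	529	9.77	4.50	62.77	7.54	na
ULC082	veryspecific	bin3	Bacteria	M	542	8.16	3.88	46.21	9.28	na
ULC082	veryspecific	bin4	Bacteria	M	120	1.72	4.73	11.13	0	na
ULC082	veryspecific	bin5	Unclassified	U	74	1.67	4.57	0	0	na
ULC082	veryspecific	nobin	Nobin	No	30077	67.18	2.15	na	na	na
ULC084	superspecific	bin1	Betaproteobacteria	M	232	23.15	5.67	93.61	1.73	na
ULC084	superspecific	bin2	Alphaproteobacteria	M	222	22.39	6.65	92.46	1.38	na
ULC084	superspecific	bin3	Cyanobacteria	C	116	21.88	20.78	98.55	0	na
ULC084	superspecific	nobin	Nobin	No	10835	32.58	1.59	na	na	na
ULC129	verysensitive	bin1	Cyanobacteria	C	299	38.35	18.46	98.64	0.77	na
ULC129	verysensitive	nobin	Nobin	No	21968	61.65	1.62	na	na	na
ULC146	superspecific	bin1	Burkholderiales	M	177	16.18	10.96	96.57	0.93	na
ULC146	superspecific	bin2	Flavobacteriaceae	M	285	12.91	6.27	94.94	0.35	na
ULC146	superspecific	bin3	Sphingomonadales	M	74	11.54	14.23	88.9	1.39	na
ULC146	superspecific	bin4	Betaproteobacteria	M	98	10.85	7.64	97.46	1.09	na
ULC146	superspecific	bin5	Alphaproteobacteria	M	350	7.56	6.25	75.87	0.32	na
ULC146	superspecific	bin6	Bacteria	M	243	3.11	4.68	10.82	0	na
ULC146	superspecific	bin7	Unclassified	U	21	1.86	12.53	8.33	0	na
ULC146	superspecific	nobin	Nobin	No	28569	35.99	1.72	na	na	na
ULC165	verysensitive	bin1	Xanthomonadaceae	M	53	15.37	24.76	99.54	0.8	na
ULC165	verysensitive	bin2	Alphaproteobacteria	M	167	14.52	7.75	96.29	1.22	na
ULC165	verysensitive	bin3	Burkholderiales	M	473	10.01	4.40	41.41	0.47	na
ULC165	verysensitive	bin4	Bacteria	C	356	6.30	3.90	24.14	1.72	na
ULC165	verysensitive	nobin	Nobin	No	19409	53.79	2.08	na	na	na
ULC179	superspecific	bin1	Alphaproteobacteria	M	247	18.89	16.30	98.54	60.19	na
ULC179	superspecific	bin2	Rhizobiales	M	261	16.95	8.86	94.78	0.94	na
ULC179	superspecific	bin3	Alphaproteobacteria	M	111	13.62	21.92	98.73	0.22	na
ULC179	superspecific	bin4	Cytophagales	M	718	13.40	4.60	67.06	0.3	na
ULC179	superspecific	bin5	Alphaproteobacteria	M	68	4.70	16.67	35.78	0	na
ULC179	superspecific	bin6	Rhizobiales	M	170	2.16	4.18	12.58	0	na
ULC179	superspecific	bin7	Unclassified	U	16	1.69	41.33	0	0	na
ULC179	superspecific	nobin	Nobin	No	13101	28.59	1.94	na	na	na
ULC186	verysensitive	bin1	Cyanobacteria	C	412	67.38	21.10	93.18	1.64	na
ULC186	verysensitive	nobin	Nobin	No	6559	32.62	1.52	na	na	na
ULC187	veryspecific	bin1	Cyanobacteria	C	62	62.18	33.11	99.29	0.47	na
ULC187	veryspecific	nobin	Nobin	No	8482	37.82	1.43	na	na	na
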