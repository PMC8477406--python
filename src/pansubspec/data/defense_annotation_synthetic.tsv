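genome_id	subspecies	n_rm_systems	has_complete_crispr	n_prophages	n_transposases	hgt_pct
Bll_rep_01	longum	1	1	2	18	22.88
Bll_rep_02	longum	1	1	3	28	25.57
Bll_rep_03	longum	1	1	3	11	23.85
Bll_rep_04	longum	1	1	0	16	24.24
Bll_rep_05	longum	2	1	2	18	22.19
Bll_rep_06	longum	2	1	2	12	23.53
Bll_rep_07	longum	2	1	2	8	21.60
Bll_rep_08	longum	2	1	3	20	23.90
Bll_rep_09	longum	2	1	3	17	23.87
Bll_rep_10	longum	2	1	1	21	21.36
Bll_rep_11	longum	2	1	2	9	21.65
Bll_rep_12	longum	2	0	2	17	22.88
Bll_rep_13	longum	2	0	3	5	22.17
Bll_rep_14	longum	2	0	3	19	23.70
Bll_rep_15	longum	3	0	3	28	21.78
Bll_rep_16	longum	3	0	2	6	21.16
Bll_rep_17	longum	3	0	2	18	21.98
Bll_rep_18	longum	3	0	3	19	21.18
Bll_rep_19	longum	3	0	0	5	20.96
Bll_rep_20	longum	3	0	2	28	21.54
Bll_rep_21	longum	4	0	2	8	20.50
Bls_rep_01	suis	0	1	0	16	24.65
Bls_rep_02	suis	1	1	3	19	21.92
Bls_rep_03	suis	1	1	1	5	20.80
Bls_rep_04	suis	1	0	3	8	22.91
Bls_rep_05	suis	2	0	1	8	19.76
Bls_rep_06	suis	2	0	1	26	20.87
Bls_rep_07	suis	2	0	2	21	19.41
Bls_rep_08	suis	2	0	3	8	20.99
Bls_rep_09	suis	2	0	3	9	19.25
Bls_rep_10	suis	4	0	0	20	18.44
Bli_rep_01	infantis	1	1	2	22	28.23
Bli_rep_02	infantis	1	1	1	22	29.54
Bli_rep_03	infantis	1	1	0	29	28.95
Bli_rep_04	infantis	1	0	1	11	28.74
Bli_rep_05	infantis	1	0	3	25	28.66
Bli_rep_06	infantis	0	0	2	28	31.39
Bli_rep_07	infantis	0	0	0	22	30.20
Bli_rep_08	infantis	0	0	1	14	29.07
Bli_rep_09	infantis	0	0	2	18	29.60
Bli_rep_10	infantis	0	0	1	7	29.63
Bli_rep_11	infantis	0	0	2	17	30.50
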