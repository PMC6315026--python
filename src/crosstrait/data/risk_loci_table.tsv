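locus	discovery	variant	role	position	risk_allele_cll	risk_allele_mm	or_cll	or_mm	p_cll	p_mm
2q31.1	MM	rs4325816	sentinel	174808899	T	T	1.11	1.12	2.0e-3	6.4e-7
2q31.1	MM	rs72919402	correlated	174750200	T	-	1.13	-	4.6e-4	-
3q26.2	MM & CLL	rs1317082	sentinel	169497585	A	A	1.20	1.19	7.1e-8	2.2e-16
3q26.2	MM & CLL	rs3821383	correlated	169489946	A	A	1.20	1.18	4.2e-8	4.5e-15
6p25.3	CLL	rs872071	sentinel	411064	G	G	1.37	1.10	2.8e-27	7.5e-7
6p25.3	CLL	rs1050976	correlated	408079	T	T	1.37	1.10	1.9e-27	3.7e-7
6p22.3	MM	rs34229995	sentinel	15244018	G	G	1.37	1.36	8.5e-3	5.6e-8
6p22.3	MM	rs13197919	correlated	15282334	T	T	1.35	1.32	1.3e-3	3.42e-7
7q31.33	MM	rs58618031	sentinel	124583896	T	T	1.15	1.11	3.2e-5	1.7e-7
7q31.33	MM	rs59294613	correlated	124554267	C	-	1.16	-	4.4e-6	-
8q24.21	MM	rs1948915	sentinel	128222421	C	C	1.17	1.15	7.6e-7	2.5e-12
10q23.31	CLL	rs6586163	sentinel	90752018	A	A	1.28	1.06	1.1e-16	1.8e-3
10q23.31	CLL	rs7082101	correlated	90741615	-	C	-	1.06	-	8.2e-4
11q23.2	CLL	rs11601504	sentinel	113526853	C	C	1.20	1.09	2.3e-5	8.5e-4
16q23.1	MM	rs7193541	sentinel	74664743	T	T	1.12	1.12	1.0e-4	3.7e-10
22q13.33	CLL	rs140522	sentinel	50971266	T	T	1.17	1.08	3.7e-7	1.2e-4
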