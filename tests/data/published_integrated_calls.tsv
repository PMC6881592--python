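cancer_type	probe	delta_beta	gene	fold_change	p_value	r	p_r
BRCA	cg05661282	0.328652	ZNF154	-2.51052	0	-0.5733	4.31e-69
BRCA	cg02938205	0.313603	CCDC36	-4.76933	0	-0.25194	1.03e-12
BRCA	cg11417025	0.340146	SOSTDC1	-3.43449	5.82e-11	-0.45553	4.54e-41
BRCA	cg17116120	0.203629	COX4I2	-2.06691	0	-0.26144	1.31e-13
BRCA	cg06087421	0.206592	TAL1	-3.82039	0	-0.24326	6.26e-12
BRCA	cg06363129	0.297534	SOSTDC1	-3.43449	5.82e-11	-0.49109	2.09e-48
BRCA	cg03757145	0.274106	CDKL2	-2.28953	2.5e-08	-0.63537	4.45e-89
BRCA	cg12042659	0.231631	ZNF132	-2.00658	0	-0.48716	1.49e-47
BRCA	cg07220448	0.29423	SOSTDC1	-3.43449	5.82e-11	-0.45009	5.08e-40
BRCA	cg10168635	0.267563	C2orf88	-5.55411	0	-0.32566	1.18e-20
BRCA	cg14625175	0.405266	HOXA10	-2.7302	0	-0.2537	7.06e-13
BRCA	cg14263942	0.281991	CDKL2	-2.28953	2.5e-08	-0.63136	1.19e-87
BRCA	cg18868483	0.301089	B3GAT2	-1.54216	4.51e-05	-0.22273	3.44e-10
BRCA	cg01454592	0.245132	CCDC36	-4.76933	0	-0.24726	2.75e-12
BRCA	cg10344081	0.294167	CDKL2	-2.28953	2.5e-08	-0.63967	1.23e-90
BRCA	cg06126713	0.395028	SOSTDC1	-3.43449	5.82e-11	-0.44907	7.94e-40
BRCA	cg24432073	0.20478	CDKL2	-2.28953	2.5e-08	-0.62519	1.73e-85
BRCA	cg02085507	0.372686	TRIP10	-1.54805	0	-0.20553	7.39e-09
BRCA	cg05308656	0.253266	ARL4C	-1.64326	6.71e-13	-0.52274	1.06e-55
BRCA	cg11270393	0.308156	ITPRIPL1	-5.73674	0	-0.39404	2.9e-30
BRCA	cg12506930	0.323833	ZNF154	-2.51052	0	-0.57088	2.14e-68
BRCA	cg07519235	0.459351	GPRC5B	-2.5035	0	-0.49936	3.06e-50
BRCA	cg21113446	0.215296	PPP2R2B	-3.10098	0	-0.33333	1.29e-21
BRCA	cg02324432	0.253122	KLHL2	-1.79165	0	-0.23855	1.62e-11
BRCA	cg04203238	0.274658	PROM1	-1.68571	0.000897	-0.64459	1.9e-92
BRCA	cg04243822	0.216055	C1QTNF1	-3.30512	0	-0.22631	1.76e-10
BRCA	cg00680551	0.424494	NCALD	-3.00007	0	-0.37035	1.14e-26
BRCA	cg27049766	0.32279	ZNF154	-2.51052	0	-0.61756	6.93e-83
BRCA	cg08816590	0.288288	PDE1B	-3.70157	0	-0.30695	2.05e-18
BRCA	cg14988503	0.210715	CDKL2	-2.28953	2.5e-08	-0.58357	4.19e-72
BRCA	cg18236571	0.263708	PABPC4L	-1.69422	2.54e-09	-0.48483	4.73e-47
BRCA	cg18085435	-0.20795	ATP8B1	1.700614	8.59e-08	-0.56131	1.05e-65
BRCA	cg01062470	-0.2649	KIF24	2.804288	0	-0.30429	4.14e-18
BRCA	cg04567302	-0.25404	SLC44A4	5.457885	0	-0.6607	1.26e-98
BRCA	cg16702815	-0.32459	AGR3	5.086635	3.09e-12	-0.69724	3.7e-114
BRCA	cg10173620	-0.29247	ABHD2	1.920326	0.000667	-0.36501	6.75e-26
BRCA	cg11819637	-0.26298	THPO	3.885221	1.36e-06	-0.67328	1e-103
BRCA	cg08960448	-0.33095	SEPT12	5.27739	7.67e-05	-0.30054	1.1e-17
BRCA	cg27530053	-0.20353	FAM83E	3.858755	8.11e-09	-0.458	1.5e-41
BRCA	cg23631538	-0.3347	DENND2D	1.578295	8.5e-13	-0.43718	1.31e-37
BRCA	cg12633764	-0.29531	MAPT	1.804312	4.72e-05	-0.72534	8.3e-128
KIRC	cg27026192	0.214365	KIFC3	-1.57694	0	-0.36061	2.72e-11
KIRC	cg02993070	0.296156	FERMT2	-1.58269	3.77e-15	-0.26413	1.59e-06
KIRC	cg02852670	0.260053	KLHL33	-3.21637	0	-0.25921	2.52e-06
KIRP	cg11800117	0.293577	C11orf75	-1.50718	3.06e-05	-0.26745	7.16e-06
KIRP	cg20962532	0.209952	KCNJ1	-32.1899	0	-0.26319	1.01e-05
KIRP	cg11968091	0.261459	ODZ4	-2.24539	0.000389	-0.30657	2.26e-07
KIRP	cg05227215	0.41792	CXXC5	-2.04975	0	-0.25958	1.35e-05
KIRP	cg04858586	0.269997	RABGAP1L	-2.15075	5.35e-13	-0.21864	0.000266
KIRP	cg03648711	0.255349	ODZ4	-2.24539	0.000389	-0.2788	2.77e-06
KIRP	cg24277788	0.243307	ACSL1	-2.44389	1.27e-14	-0.33942	8.17e-09
KIRP	cg03883256	0.265289	USP2	-3.63204	0	-0.21891	0.000261
KIRP	cg10416846	0.299733	PNOC	-4.19665	2.27e-08	-0.25688	1.67e-05
KIRP	cg24127861	0.207238	REC8	-2.2299	0.000653	-0.31031	1.58e-07
KIRP	cg15974053	0.242659	HSD17B14	-2.21561	2.94e-05	-0.73157	3.69e-47
KIRP	cg16530498	0.222937	HSD17B14	-2.21561	2.94e-05	-0.74962	1.14e-50
KIRP	cg19414598	0.214085	DMC1	-1.57414	0.010418	-0.46463	4.44e-16
KIRP	cg15731317	-0.37473	SYTL2	1.895209	0.000186	-0.50345	5.16e-19
KIRP	cg00583003	-0.28896	SPP1	2.483728	3.64e-06	-0.2564	1.73e-05
KIRP	cg21622977	-0.22364	RBPMS	1.793989	3.22e-08	-0.49531	2.29e-18
KIRP	cg17660833	-0.53805	HRH1	4.616294	2.92e-08	-0.33817	9.35e-09
KIRP	cg20306842	-0.21944	CREB5	7.099205	1.84e-10	-0.40814	2.01e-12
KIRP	cg23031196	-0.31756	SLC38A1	1.620018	0.000342	-0.37927	8.38e-11
KIRP	cg01944226	-0.28436	SLC16A3	4.39414	8.6e-06	-0.76961	6.36e-55
KIRP	cg09182455	-0.41989	CORO1C	2.191563	4e-11	-0.22222	0.000209
KIRP	cg01812894	-0.26035	ALDH1A1	2.206084	0.000791	-0.2834	1.86e-06
KIRP	cg01942558	-0.4858	TNFAIP6	45.14506	1.33e-05	-0.68008	1.51e-38
KIRP	cg09122223	-0.34216	IL18	2.298725	1.94e-07	-0.24966	2.91e-05
KIRP	cg16929739	-0.38802	HRH1	4.616294	2.92e-08	-0.32623	3.25e-08
KIRP	cg09727050	-0.39502	TNFAIP6	45.14506	1.33e-05	-0.78361	3.61e-58
KIRP	cg07042532	-0.32291	CREB5	7.099205	1.84e-10	-0.62039	1.54e-30
KIRP	cg13445177	-0.29628	S100A10	1.832289	4.18e-08	-0.34141	6.61e-09
KIRP	cg14333454	-0.30823	SFN	11.18657	0.034773	-0.7839	3.08e-58
KIRP	cg08778148	-0.2173	TFPI	2.08801	0.00022	-0.44876	5.55e-15
KIRP	cg14578677	-0.23981	TLR6	2.307439	0.007805	-0.44887	5.46e-15
KIRP	cg12669354	-0.35182	CD151	1.854554	1.27e-11	-0.37366	1.66e-10
KIRP	cg00449608	-0.3179	GPR45	3.093416	0.00448	-0.44012	2.08e-14
KIRP	cg26864526	-0.36952	HRH1	4.616294	2.92e-08	-0.53238	1.86e-21
KIRP	cg10183885	-0.26987	SLC16A3	4.39414	8.6e-06	-0.8219	1.96e-68
KIRP	cg06836480	-0.24006	DHRS9	9.536973	0.012336	-0.23825	6.8e-05
KIRP	cg11702866	-0.44443	HRH1	4.616294	2.92e-08	-0.29902	4.58e-07
KIRP	cg06457736	-0.44623	HRH1	4.616294	2.92e-08	-0.31287	1.23e-07
KIRP	cg24258705	-0.47246	MET	4.732257	1.75e-08	-0.63402	3.26e-32
KIRP	cg15717250	-0.34571	UPK1B	4.304701	0.004226	-0.66398	3.33e-36
KIRP	cg03489712	-0.29538	ZYX	1.99858	3.19e-10	-0.22033	0.000237
KIRP	cg09950681	-0.33674	PKP3	2.143401	0.047341	-0.60723	5.34e-29
KIRP	cg14550985	-0.33893	RIN1	5.119397	2.06e-10	-0.68575	2.09e-39
KIRP	cg21950166	-0.36612	SFN	11.18657	0.034773	-0.71606	2.3e-44
KIRP	cg06720467	-0.34964	SFN	11.18657	0.034773	-0.55134	3.43e-23
KIRP	cg20992002	-0.30043	PKP3	2.143401	0.047341	-0.6543	7.26e-35
KIRP	cg02872476	-0.23267	DBNDD1	3.125374	4.05e-08	-0.66917	6.07e-37
LIHC	cg21831174	0.218134	MASP1	-2.16898	0	-0.35207	1.19e-11
LIHC	cg04951797	-0.28077	SGOL1	19.52393	5.5e-07	-0.62482	2.7e-39
LIHC	cg17336139	-0.25975	PRAME	231.9457	0.018915	-0.36725	1.29e-12
LIHC	cg23213217	-0.24898	DEGS1	2.328115	2.56e-08	-0.33786	8.59e-11
LIHC	cg11225751	-0.21878	PRAME	231.9457	0.018915	-0.46426	4.12e-20
LIHC	cg06442489	-0.34313	ZSCAN18	1.965757	0.001058	-0.28886	3.75e-08
LIHC	cg20441902	-0.22001	FUT2	14.81239	0.012527	-0.54902	6.06e-29
LIHC	cg25060890	-0.22045	RPS6KC1	2.58206	2.81e-11	-0.39031	3.5e-14
LIHC	cg03368046	-0.20541	FAM186A	4.276926	0.000748	-0.24311	4.2e-06
LIHC	cg23924737	-0.25896	MRPS23	2.825878	4e-15	-0.40317	4.11e-15
LIHC	cg01999046	-0.30348	TRAF2	3.59974	4e-15	-0.48642	3.45e-22
LIHC	cg03212674	-0.22852	CLK2	3.219276	7.32e-13	-0.26115	7.25e-07
LIHC	cg02516101	-0.21135	CSNK1E	2.573716	5e-09	-0.43473	1.44e-17
LIHC	cg07303143	-0.37162	KIAA1143	1.713539	2.33e-07	-0.4433	2.79e-18
LUAD	cg04372674	0.214314	AQP1	-2.70913	7.09e-14	-0.6127	3.66e-49
LUAD	cg25075794	0.226309	AQP1	-2.70913	7.09e-14	-0.60885	2.09e-48
LUAD	cg02571816	0.216135	PPP1R14A	-3.40955	0	-0.34411	2.41e-14
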