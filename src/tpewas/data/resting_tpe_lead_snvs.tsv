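# Published discovery / replication / combined association statistics for the
# 28 lead SNVs for resting Tpe from the UK Biobank exercise-ECG GWAS.
# replicated_printed records the published bold/non-bold replication marking
# (used only to cross-check the decision rules, never read by them);
# n_secondary is the published count of secondary signals at the locus.
locus	snv_id	chrom	pos	ea	aa	eaf_disc	beta_disc	se_disc	p_disc	n_disc	eaf_repl	beta_repl	se_repl	p_repl	n_repl	eaf_comb	beta_comb	se_comb	p_comb	n_comb	replicated_printed	n_secondary
RNF207	rs10864434	1	6262231	A	T	0.602	-0.066	0.008	1.20e-15	28511	0.600	-0.054	0.007	2.50e-14	39789	0.601	-0.058	0.005	5.80e-28	68658	1	0
SSBP3	rs603901	1	54741767	C	T	0.434	-0.059	0.008	3.80e-13	29111	0.436	-0.040	0.007	7.30e-09	40626	0.435	-0.049	0.005	5.70e-21	70103	1	0
SGIP1	rs10789207	1	66991346	T	C	0.787	-0.065	0.010	2.30e-11	29383	0.784	-0.043	0.008	1.50e-07	41005	0.786	-0.054	0.006	7.50e-18	70757	1	0
KCND3	rs116532272	1	112560237	G	A	0.986	0.133	0.036	1.90e-04	26964	0.986	0.140	0.030	3.20e-06	37629	0.986	0.140	0.023	9.10e-10	64931	0	0
MEF2D	rs1050316	1	156434703	G	T	0.345	-0.070	0.008	1.30e-16	29481	0.349	-0.055	0.007	1.40e-14	41142	0.347	-0.061	0.005	9.40e-30	70993	1	0
DPT	rs607484	1	168687512	T	C	0.733	0.042	0.009	2.90e-06	29624	0.734	0.024	0.008	1.90e-03	41342	0.733	0.032	0.006	3.10e-08	71338	0	1
STRN	rs3770774	2	37192495	T	C	0.518	-0.040	0.008	7.90e-07	29310	0.520	-0.029	0.007	2.30e-05	40903	0.519	-0.032	0.005	8.20e-10	70581	1	0
SLC8A1	rs3545097	2	40754314	T	C	0.936	0.068	0.016	3.20e-05	29231	0.935	0.056	0.014	4.60e-05	40794	0.935	0.062	0.010	3.30e-09	70392	0	0
SERTAD2	rs12466865	2	64882414	C	T	0.639	-0.029	0.008	6.00e-04	28778	0.639	-0.042	0.007	4.80e-09	40161	0.639	-0.037	0.005	7.70e-12	69301	0	0
SCN5A-SCN10A	rs7373065	3	38710315	T	C	0.020	-0.149	0.030	5.70e-07	27547	0.019	-0.143	0.026	2.60e-08	38443	0.019	-0.140	0.019	3.80e-13	66336	1	2
CAMK2D	rs35132791	4	114456506	C	G	0.744	-0.053	0.009	8.90e-09	29455	0.740	-0.025	0.008	9.90e-04	41107	0.742	-0.037	0.006	3.10e-10	70932	1	0
NKX2-5	rs6882776	5	172664163	G	A	0.720	-0.039	0.009	1.10e-05	29157	0.716	-0.050	0.008	5.70e-11	40690	0.717	-0.044	0.006	1.50e-14	70213	0	0
RUFY1	rs80090179	5	178936268	T	G	0.989	-0.170	0.040	2.10e-05	27892	0.989	-0.144	0.034	2.00e-05	38925	0.989	-0.156	0.026	9.50e-10	67167	0	0
SLC35F1	rs12210810	6	118653204	G	C	0.944	0.106	0.018	1.30e-09	29624	0.945	0.123	0.015	1.20e-16	41342	0.945	0.118	0.011	4.60e-26	71338	1	0
CREB5	rs12700888	7	28409532	A	C	0.264	0.047	0.009	2.00e-07	29355	0.261	0.040	0.008	2.30e-07	40967	0.262	0.042	0.006	5.80e-13	70691	1	0
CAV2	rs17138749	7	116133098	A	C	0.838	-0.036	0.011	7.50e-04	29511	0.837	-0.042	0.009	6.00e-06	41184	0.838	-0.040	0.007	9.30e-09	71065	0	0
KCNH2	rs113843864	7	150618509	G	A	0.752	0.077	0.009	6.70e-17	29582	0.752	0.047	0.008	2.60e-09	41283	0.752	0.059	0.006	4.10e-23	71236	1	0
PRAG1	rs2976944	8	8270914	T	C	0.486	-0.040	0.008	8.10e-07	29199	0.489	-0.025	0.007	2.60e-04	40749	0.488	-0.028	0.005	3.50e-08	70315	1	0
MSRA	rs1028314	8	10241411	C	T	0.484	0.027	0.008	8.20e-04	29386	0.482	0.034	0.007	4.80e-07	41009	0.483	0.030	0.005	5.50e-09	70764	0	0
AZIN1	rs608236	8	103928940	A	G	0.433	0.030	0.008	2.70e-04	29264	0.433	0.044	0.007	1.30e-10	40839	0.433	0.038	0.005	2.80e-13	70471	0	0
ZMIZ1	rs2486695	10	80871063	G	A	0.612	-0.038	0.008	3.50e-06	29466	0.615	-0.038	0.007	4.70e-08	41121	0.613	-0.037	0.005	1.70e-12	70957	0	0
IGF1R	rs2871974	15	99284074	C	T	0.363	-0.054	0.008	1.00e-10	29500	0.358	-0.032	0.007	5.40e-06	41169	0.360	-0.042	0.005	2.90e-15	71040	1	0
LITAF	rs2080512	16	11692198	G	T	0.538	-0.035	0.008	1.60e-05	29452	0.539	-0.031	0.007	3.40e-06	41102	0.538	-0.034	0.005	2.00e-11	70924	0	1
GINS3	rs1424077	16	58462627	G	A	0.273	-0.050	0.009	1.70e-08	29486	0.275	-0.020	0.008	7.50e-03	41150	0.274	-0.033	0.006	5.60e-09	71006	0	0
KCNJ2	rs4399570	17	68479345	G	A	0.698	0.162	0.009	2.20e-78	29508	0.699	0.125	0.007	1.60e-64	41180	0.699	0.142	0.006	5.30e-143	71058	1	0
PYGB	rs55769542	20	25272895	C	CA	0.674	-0.047	0.009	3.70e-07	25533	0.674	-0.030	0.008	8.30e-05	35633	0.674	-0.037	0.006	2.60e-10	61487	1	0
DEFB118	rs36094783	20	29934214	G	A	0.932	-0.068	0.016	2.50e-05	28334	0.932	-0.050	0.014	2.70e-04	39541	0.932	-0.057	0.010	3.20e-08	68231	0	0
KCNJ4	rs196064	22	38851392	C	T	0.632	0.049	0.008	3.80e-09	29421	0.634	0.049	0.007	3.00e-12	41058	0.633	0.049	0.005	1.30e-20	70848	1	0
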