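sag_id	contigs	length_bp	longest	smallest	average	completeness_104	completeness_191
AAA261C02	79	628204	41092	2004	7952	49.0	39.8
AAA261F17	62	527268	47307	2094	8504	32.7	21.5
AAA261G05	68	532132	27533	2021	7825	50.0	39.3
AAA261O19	99	731948	41274	2022	7393	41.3	35.6
AAA261D19	82	673667	37168	2063	8215	50.0	48.7
AAA261F19	82	655981	44778	2016	7999	49.0	45.5
AAA259A05	161	1167671	38447	2002	7252	36.5	36.1
AAA259D18	56	387594	17623	2039	6921	14.4	6.8
AAA259E17	141	883132	39302	2014	6264	24.0	19.4
AAA259E19	211	1424127	37031	2003	6749	42.3	37.2
AAA259O05	152	1067938	38713	2025	7025	39.4	36.1
AAA259B11	118	828207	32654	2022	7018	19.2	23.0
AAA259D14	117	852718	37663	2014	7247	49.0	36.6
AAA259E22	100	825701	37800	2026	8257	14.4	16.8
AAA259I07	92	643115	36324	2032	6990	9.6	18.8
AAA259I09	215	1350271	42722	2011	6280	56.7	54.5
AAA259I14	121	771138	37050	2016	6373	19.2	16.2
AAA259J03	148	896033	45149	2003	6054	29.8	31.4
AAA259M10	127	865782	48524	2053	6817	12.5	18.8
AAA382A03	88	428827	17372	2040	4866	14.4	16.8
AAA382A13	72	408808	19309	2004	5677	18.2	15.7
AAA382A20	111	925397	41226	2010	8336	36.5	27.7
AAA382C18	74	546193	38914	2036	7380	12.5	15.7
AAA382F02	34	336176	29731	2226	9887	25.9	34.0
AAA382K21	35	258290	18371	2067	7379	8.7	7.9
AAA382M17	63	378040	25329	2007	6000	32.7	22.5
AAA382N08	58	422936	37140	2024	7292	7.7	8.4
AAA385D11	35	306358	26504	2012	8753	8.7	12.6
AAA385M02	16	137797	36276	2118	8612	1.0	1.0
AAA385M11	32	215229	23432	2461	6726	NA	0.5
AAA833F18	24	269215	63868	2373	11246	10.6	9.9
AAA833K04	25	162840	21872	2030	6513	26.0	15.7
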