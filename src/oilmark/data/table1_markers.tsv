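oil	no	mz	rt	rt_tol	ms2_1	ms2_2	ms2_3	ms2_4	ms2_5	ce	det1	det5
sunflower	1	231.1386	10.03	0.18	185.1318	143.0847	131.0851	159.1166	173.0958	20	+	+
sunflower	2	217.0865	11.31	0.25	43.0179	189.0539	163.0382	91.0540	147.0793	20	+	+
sunflower	3	345.0975	11.77	0.25	315.0495	182.9918	133.0644	287.0544	99.0073	40	+	+
sunflower	4	203.1076	12.76	0.24	43.0181	77.0385	91.0539	145.0642	107.0487	40	+	+
sunflower	5	301.2172	13.15	0.2	255.2104	119.0851	107.0853	145.1007	133.1008	20	+	+
sunflower	6	392.2444	14.14	0.26	315.1955	269.1898	297.1844	161.0956	147.0800	20	+	+
sunflower	7	420.2758	16.76	0.3	315.1955	269.1898	297.1845	161.0956	251.1790	20	+	+
sunflower	8	432.2758	17.47	0.28	315.1957	269.1899	297.1845	161.0956	397.2364	20	+	+
sunflower	9	434.2913	17.98	0.33	315.1957	297.1846	296.1899	161.0957	333.2044	20	+	+
sunflower	10	576.3394	19.44	0.26	541.3012	457.2439	499.2907	57.0697	85.0645	10	+	+
sunflower	11	590.3552	20.23	0.31	555.3190	471.2605	57.0696	369.1917	85.0645	20	+	+
sunflower	12	604.3699	20.97	0.3	485.2759	569.3337	57.0697	85.0646	383.2070	20	+	+
sunflower	13	618.3865	21.74	0.26	499.2917	57.0696	583.3493	85.0644	397.2225	20	+	+
rapeseed	14	162.0557	6.01	0.28	134.0597	116.0491	106.0648	79.0541	89.0383	20	+	+
rapeseed	15	225.1488	6.44	0.16	69.0698	111.0797	165.1268	43.0183	123.1160	20	+	+
rapeseed	16	288.1237	10.05	0.13	212.0713	230.0797	156.0798	81.0701	272.0908	35	+	+
rapeseed	17	467.3510	20.42	0.3	57.0699	155.0107	238.9294	314.0962	419.3015	45	+	+
rapeseed	18	483.3824	22.01	0.18	45.0304	89.0596	153.0190	264.9438	321.2125	45	-	+
rapeseed	19	379.3365	24.26	0.34	69.0698	83.0854	57.0701	295.2418	323.2717	20	-	+
rapeseed	20	413.3429	24.81	0.34	69.0708	395.3291	83.0859	271.2046	315.2671	30	+	+
rapeseed	21	773.5184	27.95	0.7	493.2745	521.3057	309.2407	91.0394	73.0289	45	+	+
sesame	22	373.1286	8.71	0.15	355.1166	151.0383	205.0850	337.1064	137.0588	10	-	+
sesame	23	371.1136	10.6	0.19	353.1019	203.0700	335.0913	149.0231	135.0440	10	+	+
sesame	24	299.2592	12.88	0.07	281.2471	263.2366	121.1008	71.0491	135.1165	10	-	+
sesame	25	337.1082	13.66	0.22	135.0438	289.0856	261.0903	185.0590	319.0959	20	+	+
sesame	26	173.0604	14.53	0.23	143.0485	115.0539	131.0487	155.0483	65.0381	10	+	+
flax	27	212.0823	8.93	0.26	167.0600	195.0551	140.0488	185.0704	97.9609	20	-	+
flax	28	287.2016	10.45	0.08	121.0642	93.0694	105.0694	148.0878	79.0541	40	-	+
flax	29	285.1853	11.13	0.1	148.0878	187.1114	105.0694	133.0642	199.1109	40	-	+
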