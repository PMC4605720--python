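Age	1975-1979	1980-1984	1985-1989	1990-1994	1995-1999	2000-2004	2005-2009
20-24	3	6	7	10	6	7	4
25-29	18	26	3	16	19	24	21
30-34	23	28	49	42	40	38	47
35-39	63	61	64	84	90	85	91
40-44	118	102	139	162	158	137	142
45-49	231	200	209	210	240	289	314
50-54	410	361	312	303	324	392	442
55-59	576	573	522	435	443	504	558
60-64	795	783	780	651	569	555	633
65-69	798	940	866	843	710	649	641
70-74	742	830	927	950	825	696	633
75-79	649	644	759	711	780	684	631
80-84	447	491	469	471	503	581	498
85-89	206	253	239	276	260	277	308
90-94	71	76	82	94	85	78	94
95-99	12	22	17	17	20	12	11
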