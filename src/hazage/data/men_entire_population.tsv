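Age	1975-1979	1980-1984	1985-1989	1990-1994	1995-1999	2000-2004	2005-2009
20-24	4823448	5066913	4740361	4468579	4345198	4794672	4950981
25-29	4557117	5107569	5314620	5037570	4919617	4721690	4971495
30-34	3854083	4647582	5174288	5519031	5373101	5151259	4785983
35-39	3031712	3764909	4578026	5224678	5602105	5283839	5053627
40-44	2655844	2980012	3763370	4646871	5199589	5447194	5177116
45-49	2688338	2573983	2944425	3692897	4529835	5046921	5308329
50-54	2757647	2596258	2495095	2851472	3635290	4432905	4911526
55-59	2517854	2563881	2413126	2360030	2719212	3433799	4234026
60-64	2078337	2251967	2289385	2217312	2184372	2488027	3190864
65-69	1595444	1788748	1963592	2014472	1958011	1927699	2259769
70-74	1134899	1291607	1445855	1621767	1694793	1674177	1690403
75-79	736030	843325	982036	1136567	1302277	1380812	1375331
80-84	440318	469740	542595	650905	786468	920646	1010045
85-89	202239	229444	252456	294440	362880	435645	539711
90-94	69129	78429	86295	100646	124040	148913	184484
95-99	15213	17260	18991	22149	27297	32771	40599
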