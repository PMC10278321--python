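# Raw transcription of the printed rise-time table (decimal commas as printed).
# Columns: P(cmH2O) | Pajunk Sprotte M1 M2 M3 | M. Schilling M1 M2 M3 | Braun Spinocan M1 M2 M3
# Early single-digit-height entries printed without a separator (e.g. '7477' = 7,477 s).
1	7,477	7,297	7,664	11,223	11,484	11,529	13,843	13,414	14,705
2	15,262	15,119	15,226	23,453	23,559	23,418	29,669	29,356	30,154
3	23,532	23,608	23,465	36,503	36,263	36,098	46,654	46,242	47,304
4	32,746	32,903	32,833	50,713	50,764	50,099	65,669	64,521	64,483
5	42,85	43,497	43,014	66,54	66,495	66,246	86,268	84,756	84,804
6	54,429	54,859	54,507	84,133	84,582	83,735	109,424	107,42	107,443
7	67,493	67,913	67,464	103,875	104,351	103,339	135,146	132,06	132,327
8	82,794	83,742	82,705	126,741	127,224	125,766	164,203	161,072	161,821
9	99,915	101,705	100,722	153,524	154,463	152,368	199,339	195,063	196,323
10	121,72	123,534	120,855	182,494	186,791	183,667	242,336	234,635	236,528
11	149,557	152,16	149,105	225,71	227,57	223,957	296,737	286,846	288,835
12	188,186	191,823	187,137	280,662	282,595	277,612	369,026	354,984	359,79
13	254,348	262,977	251,124	365,752	368,164	360,552	486,537	456,29	469,991
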