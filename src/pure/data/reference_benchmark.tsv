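experiment_id	geo_id	organism	true_cdt	hypothesis	pure_rank_of_true	pure_n_significant
1	GSE26487	Human	Dexamethasone	H1	1	1
2	GSE49804	Mouse	Dexamethasone	H1	2	4
3	GSE86837	Mouse	Diethylhexyl Phthalate	H1	1	1
4	GSE58434_H	Human	Calcitriol	H1	1	13
5	GSE58434_Ast	Human	Calcitriol	H1	2	8
6	GSE11352_12h	Human	Estradiol	H1	1	28
7	GSE11352_24h	Human	Estradiol	H1	1	25
8	GSE11352_48h	Human	Estradiol	H1	2	31
9	GSE74000	Human	Acetaminophen	H1	1	17
10	GSE12446	Human	Estradiol	H1	4	33
11	GSE67266_WT	Mouse	Etoposide	H1	6	20
12	GSE67266_KO	Mouse	Etoposide	H1	7.5	22
13	GSE51213	Mouse	Dexamethasone	H1	9	66
14	GSE58875	Rat	Copper deficiency	H1	1	2
15	GSE147507_NHBE	Human	Methylprednisolone	H2	2.5	8
16	GSE147507_A549	Human	Methylprednisolone	H2	4	12
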