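year	ytwrmt	tgsgy	twp	tpsa	pwpia	psapia	ptssa	nss
2004	862 860	7.95 × 10^10^	6.43 × 10^9^	47 291 610	14	8.43	0.245	385/0.0008
2005	830 175	1.41 × 10^11^	6.51 × 10^9^	47 880 595	16	7.49	0.171	385/0.0008
2006	721 795	2.31 × 10^11^	6.59 × 10^9^	48 489 464	17	7.61	0.095	385/0.0008
2007	650 083	3.72 × 10^11^	6.67 × 10^9^	49 119 766	20	8.07	0.059	385/0.0008
2008	736 690	6.11 × 10^11^	6.76 × 10^9^	49 779 472	23	8.43	0.045	385/0.0008
2009	676 660	7.04 × 10^11^	6.84 × 10^9^	50 477 013	26	10.00	0.034	385/0.0008
2010	836 685	1.16 × 10^12^	6.92 × 10^9^	51 216 967	29	24.00	0.012	385/0.0008
2011	766 485	1.42 × 10^12^	7.00 × 10^9^	52 003 759	31	33.97	0.007	385/0.0007
2012	802 045	1.21 × 10^12^	7.09 × 10^9^	52 832 659	34	41.00	0.007	385/0.0007
2013	817 385	2.16 × 10^12^	7.18 × 10^9^	53 687 125	36	46.50	0.004	385/0.0007
2014	907 155	2.10 × 10^12^	7.26 × 10^9^	54 544 184	38	49.00	0.004	385/0.0007
2015	1 043 335	2.83 × 10^12^	7.35 × 10^9^	55 386 369	40	51.92	0.004	385/0.0007
2016	1 151 075	2.00 × 10^12^	7.43 × 10^9^	56 207 649	43	54.00	0.006	385/0.0007
2017	1 224 780	2.23 × 10^12^	7.52 × 10^9^	57 009 751	46	56.17	0.006	385/0.0007
2018	1 281 265	2.23 × 10^12^	7.60 × 10^9^	57 792 520	49	62.40	0.006	385/0.0007
2019	1 250 560	2.04 × 10^12^	7.68 × 10^9^	58 558 267	54	68.20	0.006	385/0.0007
2020	1 362 510	2.23 × 10^12^	7.76 × 10^9^	59 308 690	60	70.00	0.007	385/0.0006
2021	1 227 670	2.23 × 10^12^	7.84 × 10^9^	60 114 695	65	74.00	0.006	385/0.0006
2022	1 519 110	2.23 × 10^12^	7.92 × 10^9^	60 931 654	70	79.00	0.008	385/0.0006
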