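year	ytwrmt	atbw	atbs	athwf	mcufry	rdwdr
2004	862 860	86.641	62.975	Not reported; 0	77.7	115.4
2005	830 175	87.164	64.016	Not reported; 0	78.8	115.8
2006	721 795	87.678	65.048	Not reported; 0	79.2	115.2
2007	650 083	88.183	66.072	Not reported; 0	75.3	108.5
2008	736 690	88.678	67.086	Not reported; 0	68.9	98.3
2009	676 660	89.163	68.091	Not reported; 0	60.3	85.2
2010	836 685	89.638	69.087	Not reported; 0	52.0	72.8
2011	766 485	90.105	70.072	Not reported; 0	45.6	63.3
2012	802 045	90.562	71.048	43.3	41.5	53.9
2013	817 385	91.009	72.014	61.8	39.3	49.4
2014	907 155	91.447	72.969	62.5	37.6	46.9
2015	1 043 335	91.876	73.914	62.6	36.3	44.9
2016	1 151 075	92.296	74.848	63.3	35.2	43.2
2017	1 224 780	92.707	75.771	63.0	34.6	42.1
2018	1 281 265	93.109	76.683	55.8	33.9	41.3
2019	1 250 560	93.501	77.584	55.0	33.0	40.0
2020	1 362 510	93.885	78.475	58.7	32.2	38.6
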