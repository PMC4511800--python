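platform	n_snps	n_selected	pct_reported	se_reported	consistent
Affymetrix 250K	250000	2115	0.85	0.02	1
Affymetrix 5.0	500500	3368	0.67	0.01	1
Affymetrix 6.0	906600	6376	0.70	0.01	1
Human Exome 12v1	240000	314	0.63	0.01	0
Illumina Human1M	1000000	8934	0.89	0.01	1
Illumina HumanHap550	550000	4984	0.91	0.01	1
Illumina HumanHap650	650000	5849	0.90	0.01	1
Illumina OmniExpress	730500	5808	0.80	0.01	1
Illumina Omni Express Exome	730500	5571	0.76	0.01	1
Illumina OmniChip 2.5M	2015000	5650	0.58	0.01	0
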