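disease	mira	n_snps	se_reported	consistent
Crohn's disease	0.61	151	0.04	1
Rheumatoid arthritis	0.68	120	0.04	1
Inflammatory bowel disease	0.50	116	0.05	1
Breast cancer	0.64	85	0.05	1
Type 2 diabetes	0.51	79	0.06	1
Ulcerative colitis	0.56	77	0.06	1
Prostate cancer	0.63	71	0.06	1
Coronary heart disease	0.61	56	0.07	1
Obesity	0.55	55	0.07	1
Systemic lupus erythematosus	0.71	55	0.06	1
Schizophrenia	0.47	47	0.07	1
Age-related macular degeneration	0.52	42	0.08	1
Myopia (pathological)	0.72	51	0.07	0
Type 1 diabetes	0.55	38	0.08	1
Alzheimer's disease (late onset)	0.58	36	0.08	1
Parkinson's disease	0.55	33	0.09	1
Colorectal cancer	0.66	32	0.09	1
Celiac disease	0.59	32	0.09	1
Asthma	0.58	31	0.09	1
Psoriasis	0.61	28	0.09	1
Chronic lymphocytic leukemia	0.54	28	0.10	1
Chronic kidney disease	0.96	27	0.04	1
Primary biliary cirrhosis	0.63	27	0.09	1
Multiple sclerosis	0.60	25	0.10	1
Graves' disease	0.45	22	0.11	1
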