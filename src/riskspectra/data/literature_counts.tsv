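disease	n_disease	n_env	n_lifestyle
Obesity	210416	7892	15834
Type 2 diabetes	113333	2180	6477
Major depressive disorder	96868	3626	3466
Asthma	147762	9239	1152
Atopic dermatitis	19705	1100	144
Autism	28552	1437	98
Attention deficit hyperactivity disorder	25208	1160	164
Melanoma	98871	4546	237
Schizophrenia	112478	4004	949
Bipolar disorder	38944	1016	524
Coronary heart disease	262453	4267	5647
Psoriasis	37149	1208	167
Type 1 diabetes	68482	1561	875
Alzheimer's disease (late onset)	2958	56	35
Multiple sclerosis	63493	1565	331
Age-related macular degeneration	21515	506	111
Migraine	29512	569	264
Sudden cardiac arrest	25821	487	229
Breast cancer	292315	4727	2742
Migraine with aura	4446	89	23
Amyotrophic lateral sclerosis	18004	394	49
Amyotrophic lateral sclerosis (sporadic)	18004	394	49
Inflammatory bowel disease	74179	1425	351
Prostate cancer	123622	1855	1040
Colorectal cancer	172036	2470	1356
Crohn's disease	41342	732	178
Ulcerative colitis	36344	600	168
Parkinson's disease	76837	1368	248
Lung cancer	245974	4112	916
Myopia (pathological)	3990	77	2
Chronic kidney disease	117185	1281	961
Endometriosis	21212	342	59
Bladder cancer	62487	884	289
Systemic sclerosis	22938	387	36
Systemic lupus erythematosus	58576	929	110
Rheumatoid arthritis	120346	1578	393
Testicular germ cell tumor	27123	313	99
Ovarian cancer	86537	888	353
Graves' disease	18020	196	45
Celiac disease	20718	213	55
Acute lymphoblastic leukemia	32530	335	57
Chronic lymphocytic leukemia	19285	209	23
Pancreatic cancer	73158	622	172
Primary biliary cirrhosis	12347	93	25
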