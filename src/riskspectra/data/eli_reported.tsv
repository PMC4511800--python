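disease	eli
Obesity	112.8
Type 2 diabetes	76.4
Major depressive disorder	73.2
Asthma	70.3
Atopic dermatitis	63.1
Autism	53.8
Attention deficit hyperactivity disorder	52.5
Melanoma	48.4
Schizophrenia	44.0
Bipolar disorder	39.5
Coronary heart disease	37.8
Psoriasis	37.0
Type 1 diabetes	35.6
Alzheimer's disease (late onset)	30.8
Multiple sclerosis	29.9
Age-related macular degeneration	28.7
Migraine	28.2
Sudden cardiac arrest	27.7
Breast cancer	25.6
Migraine with aura	25.2
Amyotrophic lateral sclerosis	24.6
Amyotrophic lateral sclerosis (sporadic)	24.6
Inflammatory bowel disease	23.9
Prostate cancer	23.4
Colorectal cancer	22.2
Crohn's disease	22.0
Ulcerative colitis	21.1
Parkinson's disease	21.0
Lung cancer	20.4
Myopia (pathological)	19.8
Chronic kidney disease	19.1
Endometriosis	18.9
Bladder cancer	18.8
Systemic sclerosis	18.4
Systemic lupus erythematosus	17.7
Rheumatoid arthritis	16.4
Testicular germ cell tumor	15.2
Ovarian cancer	14.3
Graves' disease	13.4
Celiac disease	12.9
Acute lymphoblastic leukemia	12.1
Chronic lymphocytic leukemia	12.0
Pancreatic cancer	10.9
Primary biliary cirrhosis	9.6
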