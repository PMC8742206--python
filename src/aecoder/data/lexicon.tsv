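cui	semantic_type	term	preferred
C0035243	disease or syndrome	respiratory tract infection	1
C0042029	disease or syndrome	urinary tract infection	1
C3714514	disease or syndrome	infection	1
C0032227	disease or syndrome	pleural effusion	1
C0032227	disease or syndrome	pleural effusion disorder	0
C0032326	disease or syndrome	pneumothorax	1
C0040822	sign or symptom	tremor	1
C0042963	sign or symptom	vomiting	1
C0013404	sign or symptom	dyspnea	1
C0013404	sign or symptom	shortness of breath	0
C0008031	sign or symptom	chest pain	1
C0020598	disease or syndrome	hypocalcemia	1
C0020461	disease or syndrome	hyperkalemia	1
C0003123	finding	loss of appetite	1
C0003123	finding	anorexia	0
C0024117	disease or syndrome	chronic obstructive airway disease	1
C0024117	disease or syndrome	copd	0
C0030193	sign or symptom	pain	1
C0004604	sign or symptom	back pain	1
C0587597	finding	decreased mobility	1
C0221198	finding	lesion	1
C0027497	sign or symptom	nausea	1
C0018681	sign or symptom	headache	1
C0011991	sign or symptom	diarrhea	1
C0011991	sign or symptom	diarrhoea	0
C0015967	sign or symptom	pyrexia	1
C0015967	sign or symptom	fever	0
C0015672	sign or symptom	fatigue	1
C0002871	disease or syndrome	anemia	1
C0002871	disease or syndrome	anaemia	0
C0243026	pathological function	sepsis	1
C0009806	sign or symptom	constipation	1
C0011175	disease or syndrome	dehydration	1
C0012833	sign or symptom	dizziness	1
C0015230	sign or symptom	rash	1
C0010200	sign or symptom	cough	1
C0027947	disease or syndrome	neutropenia	1
C0746883	disease or syndrome	febrile neutropenia	1
C0040034	disease or syndrome	thrombocytopenia	1
C0034065	disease or syndrome	pulmonary embolism	1
C0149871	disease or syndrome	deep vein thrombosis	1
C0004238	disease or syndrome	atrial fibrillation	1
C0020649	finding	hypotension	1
C0020651	finding	orthostatic hypotension	1
C0020538	disease or syndrome	hypertension	1
C0020625	disease or syndrome	hyponatremia	1
C0020621	disease or syndrome	hypokalemia	1
C0020615	disease or syndrome	hypoglycemia	1
C0020456	finding	hyperglycemia	1
C0035078	disease or syndrome	renal failure	1
C0032285	disease or syndrome	pneumonia	1
C0007642	disease or syndrome	cellulitis	1
C0009676	sign or symptom	confusion	1
C0036572	sign or symptom	seizure	1
C0039070	sign or symptom	syncope	1
C1262477	finding	weight loss	1
C0002170	disease or syndrome	alopecia	1
C0002170	disease or syndrome	hair loss	0
C0333355	disease or syndrome	mucositis	1
C0038362	disease or syndrome	stomatitis	1
C0000737	sign or symptom	abdominal pain	1
C0027051	disease or syndrome	myocardial infarction	1
C0038454	disease or syndrome	stroke	1
C0019080	pathological function	hemorrhage	1
C0022116	pathological function	ischemia	1
C0007786	pathological function	cerebrovascular ischemia	1
C0392386	finding	hemoglobin decreased	1
C0016658	injury or poisoning	fracture	1
C0000921	injury or poisoning	fall	1
C0013221	injury or poisoning	drug toxicity	1
C0043246	injury or poisoning	wound infection	0
C0043246	injury or poisoning	laceration	1
C0027651	neoplastic process	neoplasm	1
C0027651	neoplastic process	tumor	0
C0027627	neoplastic process	metastasis	1
C0006826	neoplastic process	malignant neoplastic disease	1
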