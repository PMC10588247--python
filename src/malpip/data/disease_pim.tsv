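criterion_id	section	condition_code	drug_targets	exceptions	qualifier_notes
dp_heart_failure	circulatory	heart_failure	non-cox-2 selective nsaids|cox-2 selective inhibitors|thiazolidinediones|non-dihydropyridine calcium channel blockers|digoxin|tricyclic antidepressants|sildenafil|tadalafil|vardenafil
dp_syncope	circulatory	syncope	donepezil|rivastigmine|galantamine|non-selective alpha blockers|tricyclic antidepressants|benzodiazepines|antipsychotics|methyldopa|venlafaxine
dp_bradycardia	circulatory	bradycardia	beta blockers|donepezil|rivastigmine|galantamine|non-dihydropyridine calcium channel blockers
dp_arrhythmias	circulatory	arrhythmias	antiarrhythmics|tricyclic antidepressants|antipsychotics|donepezil|quinine
dp_hypertension	circulatory	hypertension	loop diuretics|non-selective alpha blockers|nsaids|thiazide diuretics|methyldopa
dp_htn_incontinence	circulatory	hypertension_with_urinary_incontinence	loop diuretics
dp_ankle_oedema	circulatory	dependent_ankle_oedema	loop diuretics|calcium channel blockers
dp_hypokalemia	circulatory	hypokalemia	thiazide diuretics|digoxin|fludrocortisone|loop diuretics
dp_hyponatremia	circulatory	hyponatremia	thiazide diuretics|ssris
dp_hypercalcemia	circulatory	hypercalcemia	thiazide diuretics
dp_hyperkalemia	circulatory	hyperkalemia	ace inhibitors|angiotensin receptor blockers|spironolactone
dp_bleeding_risk	circulatory	high_bleeding_risk	antiplatelets|vitamin k antagonists|direct thrombin inhibitors|factor xa inhibitors|nsaids		e.g. coagulopathy
dp_first_dvt	circulatory	first_deep_vein_thrombosis	vitamin k antagonists|direct thrombin inhibitors|factor xa inhibitors		first episode without continuing provoking risks
dp_conduction	circulatory	cardiac_conduction_abnormalities	tricyclic antidepressants|digoxin|verapamil|amiodarone|acetylcholinesterase inhibitors|beta blockers
dp_orthostatic	circulatory	orthostatic_hypotension	non-selective alpha blockers|calcium channel blockers|long-acting nitrates|chlorpromazine|tricyclic antidepressants|hydralazine|thiazide diuretics|loop diuretics|dopamine agonists|selegiline|antipsychotics|sglt inhibitors	levodopa	dopamine agonists except levodopa
dp_acs	circulatory	acute_coronary_syndrome	cox-2 selective inhibitors|non-cox-2 selective nsaids
dp_raynaud	circulatory	raynaud_disease	beta blockers
dp_cognitive	nervous	cognitive_impairment_spectrum	urological antimuscarinics|first generation antihistamines|antiparkinsonian anticholinergics|antiemetics|muscle relaxants|tricyclic antidepressants|paroxetine|antipsychotics|disopyramide|intestinal antispasmodics|psychostimulants|barbiturates|benzodiazepines|zolpidem|deferoxamine|testosterone|systemic corticosteroids|dopamine agonists|antiepileptics		delirium, dementia or cognitive impairment
dp_falls	nervous	falls_or_fractures	antipsychotics|benzodiazepines|zolpidem|opioids|tricyclic antidepressants|antiepileptics|first generation antihistamines|non-selective alpha blockers|non-selective beta blockers|paroxetine|duloxetine|loop diuretics
dp_parkinson	nervous	parkinson_disease	antipsychotics|antiemetics|trihexyphenidyl	quetiapine|clozapine	antipsychotics except quetiapine and clozapine
dp_bpsd	nervous	bpsd	antipsychotics|antiepileptics|benzodiazepines		anticonvulsants encoded as antiepileptics
dp_insomnia	nervous	insomnia	antipsychotics|psychostimulants|theophylline|pseudoephedrine|benzodiazepines|barbiturates|tricyclic antidepressants|z-hypnotics		temazepam could be considered for short-term use
dp_tremor	nervous	benign_essential_tremor	levodopa and dopamine agonists|trihexyphenidyl
dp_depression	nervous	depression	centrally acting antihypertensives|tricyclic antidepressants
dp_seizures	nervous	epilepsy	antipsychotics|bupropion|antidepressants|beta-lactam antibiotics|theophylline|h2 receptor antagonists|levodopa|isoniazid|opioids
dp_peptic_ulcer	gastrointestinal	peptic_ulcer_history	aspirin|non-cox-2 selective nsaids|systemic corticosteroids
dp_esophageal	gastrointestinal	esophageal_ulcer_dysphagia	oral bisphosphonates
dp_constipation	gastrointestinal	constipation	anticholinergics|verapamil|oral iron|opioids|aluminium antacids|tricyclic antidepressants|calcium supplements|diuretics
dp_ckd	genitourinary	chronic_kidney_disease	non-cox-2 selective nsaids|cox-2 selective inhibitors|glibenclamide|digoxin|dabigatran|metformin|oral bisphosphonates|colchicine|thiazide diuretics|factor xa inhibitors|donepezil|memantine|cimetidine|ciprofloxacin|gabapentin|proton pump inhibitors|ace inhibitors|angiotensin receptor blockers|warfarin|allopurinol|opioids|aminoglycosides|amphotericin b|vancomycin|acyclovir|clopidogrel|ticlopidine
dp_bph	genitourinary	benign_prostatic_hyperplasia	anticholinergics|tricyclic antidepressants|antimuscarinic bronchodilators
dp_incontinence	genitourinary	urinary_incontinence	non-selective alpha blockers|tricyclic antidepressants|diuretics
dp_asthma	respiratory	bronchial_asthma	non-selective beta blockers|benzodiazepines
dp_copd	respiratory	copd	theophylline|non-selective beta blockers|benzodiazepines
dp_resp_failure	respiratory	respiratory_failure	benzodiazepines|opioids|alcohol|cocaine|amphetamine		acute or chronic respiratory failure
dp_sleep_apnea	respiratory	sleep_apnea	benzodiazepines
dp_glaucoma	other	narrow_angle_glaucoma	tricyclic antidepressants|antimuscarinic bronchodilators|anticholinergics|urological antimuscarinics
dp_oa_op	other	osteoarthritis_or_osteoporosis	systemic corticosteroids|calcium supplements|nsaids|eperisone	route:intra-articular	systemic corticosteroids except intra-articular; high dose calcium supplements
dp_pain	other	chronic_pain	opioids|benzodiazepines|tramadol		opioids in chronic mild pain; long-acting opioids without short-acting opioids in breakthrough pain
dp_gout	other	gout	loop diuretics|colchicine
dp_diabetes	other	diabetes_mellitus	beta blockers|systemic corticosteroids|olanzapine|quetiapine|risperidone
dp_breast_cancer	other	breast_cancer	oestrogens
dp_vte	other	venous_thromboembolism	oestrogens
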