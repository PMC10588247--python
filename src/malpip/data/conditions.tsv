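condition_code	display_name	synonyms	any_of	all_of
heart_failure	Heart failure	congestive heart failure|systolic heart failure|chf
syncope	Syncope	fainting
bradycardia	Bradycardia
arrhythmias	Arrhythmias	arrythmias|cardiac arrhythmia
hypertension	Hypertension	high blood pressure|htn
urinary_incontinence	Urinary incontinence	incontinence
hypertension_with_urinary_incontinence	Hypertension with urinary incontinence			hypertension|urinary_incontinence
dependent_ankle_oedema	Dependent ankle oedema	ankle edema|ankle oedema
hypokalemia	Hypokalemia	hypokalaemia|low potassium
hyponatremia	Hyponatremia	hyponatraemia|low sodium
hypercalcemia	Hypercalcemia	hypercalcaemia
hyperkalemia	Hyperkalemia	hyperkalaemia
high_bleeding_risk	High bleeding risk	coagulopathy|bleeding risk
first_deep_vein_thrombosis	First deep vein thrombosis	first dvt
cardiac_conduction_abnormalities	Cardiac conduction abnormalities and heart block	heart block|conduction abnormality
orthostatic_hypotension	Orthostatic hypotension	postural hypotension
acute_coronary_syndrome	Acute coronary syndrome	acute coronary symptoms|acs
raynaud_disease	Raynaud disease	raynaud's disease|raynaud phenomenon
delirium	Delirium
dementia	Dementia
cognitive_impairment	Cognitive impairment	mild cognitive impairment
cognitive_impairment_spectrum	Delirium, dementia or cognitive impairment		delirium|dementia|cognitive_impairment
falls	Falls	history of falls|recurrent falls
fractures	Fractures	history of fractures
falls_or_fractures	History of falls or fractures		falls|fractures
parkinson_disease	Parkinson disease and parkinsonism	parkinson's disease|parkinsonism|idiopathic parkinson disease
bpsd	Behavioural and psychological symptoms of dementia	behavioral and psychological symptoms in dementia
insomnia	Sleep disorders or insomnia	sleep disorder|sleep disorders
benign_essential_tremor	Benign essential tremor	essential tremor
depression	Depression	depressive disorder
epilepsy	Seizures or epilepsy	seizures|seizure disorder
peptic_ulcer_history	History of gastric or duodenal ulcers	gastric ulcer|duodenal ulcer|peptic ulcer disease
esophageal_ulcer_dysphagia	History of esophageal ulcers and dysphagia	oesophageal ulcer|dysphagia
constipation	Constipation	chronic constipation
chronic_kidney_disease	Chronic kidney disease	ckd|renal impairment
benign_prostatic_hyperplasia	Benign prostatic hyperplasia	bph|prostatic hypertrophy
bronchial_asthma	Bronchial asthma	asthma
copd	Chronic obstructive pulmonary disease	chronic obstructive airway disease|coad
respiratory_failure	Acute or chronic respiratory failure	respiratory failures
sleep_apnea	Sleep apnea	sleep apnoea|obstructive sleep apnea
narrow_angle_glaucoma	Narrow angle glaucoma	angle-closure glaucoma
osteoarthritis	Osteoarthritis
osteoporosis	Osteoporosis
osteoarthritis_or_osteoporosis	Osteoarthritis and osteoporosis		osteoarthritis|osteoporosis
chronic_pain	Pain	chronic mild pain
gout	Gout
diabetes_mellitus	Diabetes mellitus	diabetes|type 2 diabetes|t2dm
breast_cancer	Breast cancer
venous_thromboembolism	Venous thromboembolism	vte|pulmonary embolism
chronic_atrial_fibrillation	Chronic atrial fibrillation	atrial fibrillation|af
coronary_artery_disease	Coronary artery disease	coronary vascular disease|cad
cerebrovascular_disease	Cerebrovascular disease	cerebral vascular disease|stroke history
peripheral_vascular_disease	Peripheral vascular disease	peripheral arterial disease|pvd
vascular_disease	Documented coronary, cerebral or peripheral vascular disease		coronary_artery_disease|cerebrovascular_disease|peripheral_vascular_disease
ischaemic_heart_disease	Ischaemic heart disease	ischemic heart disease|ihd	coronary_artery_disease
chronic_hypoxaemia	Documented chronic hypoxaemia	chronic hypoxemia
major_depression	Persistent major depressive symptoms	major depressive disorder
alzheimer_or_lewy_dementia	Mild-moderate Alzheimer or Lewy body dementia	alzheimer's dementia|lewy body dementia
open_angle_glaucoma	Primary open-angle glaucoma	open angle glaucoma
severe_anxiety	Persistent severe anxiety	generalised anxiety disorder
restless_legs_syndrome	Restless legs syndrome	rls
iron_deficiency	Iron deficiency	iron deficiency anaemia
severe_renal_failure	Severe renal failure	end-stage renal disease|esrf
severe_gord	Severe gastro-oesophageal reflux disease or peptic stricture	severe gerd|peptic stricture
diverticulosis	Diverticulosis	diverticular disease
active_rheumatoid_arthritis	Active disabling rheumatoid disease	rheumatoid arthritis
fragility_fracture	Previous fragility fracture	fragility fractures
housebound	Housebound
recurrent_gout	Recurrent episodes of gout	recurrent gout
diabetic_renal_disease	Diabetic renal disease	diabetic nephropathy|proteinuria|microalbuminuria
symptomatic_prostatism	Symptomatic prostatism	prostatism
atrophic_vaginitis	Symptomatic atrophic vaginitis	atrophic vaginitis
moderate_severe_pain	Moderate-severe pain	severe pain
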