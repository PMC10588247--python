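criterion_id	domain	trigger	indicated	exception	final_status	notes
ppo_af_anticoagulant	Cardiovascular system	cond:chronic_atrial_fibrillation	vitamin k antagonists|direct thrombin inhibitors|factor xa inhibitors		PPO
ppo_antiplatelet_vascular	Cardiovascular system	cond:vascular_disease	aspirin|clopidogrel|prasugrel|ticagrelor		PPO	documented coronary, cerebral or peripheral vascular disease
ppo_antihypertensive	Cardiovascular system	meas:sbp_mmHg>160 ; meas:dbp_mmHg>90 ; cond:diabetes_mellitus & meas:sbp_mmHg>140	antihypertensives		PPO	single-visit blood pressure used in place of "consistently" elevated readings
ppo_statin_vascular	Cardiovascular system	cond:vascular_disease	statins	flag:end_of_life ; age>85	PPO
ppo_acei_hf_cad	Cardiovascular system	cond:heart_failure ; cond:coronary_artery_disease	ace inhibitors		PPO	systolic heart failure and/or documented coronary artery disease
ppo_bb_ihd	Cardiovascular system	cond:ischaemic_heart_disease	beta blockers		PPO
ppo_bb_hf	Cardiovascular system	cond:heart_failure	bisoprolol|nebivolol|metoprolol|carvedilol		PPO	stable systolic heart failure
ppo_inhaled_bronchodilator	Respiratory system	cond:bronchial_asthma ; cond:copd	inhaled bronchodilators		PPO	mild to moderate asthma or COPD
ppo_inhaled_corticosteroid	Respiratory system	cond:bronchial_asthma ; cond:copd	inhaled corticosteroids		PPO	moderate-severe asthma or COPD; severity not modelled
ppo_home_oxygen	Respiratory system	cond:chronic_hypoxaemia	oxygen		PPO
ppo_levodopa_parkinson	Central nervous system and eyes	cond:parkinson_disease	levodopa and dopamine agonists		PPO	idiopathic Parkinson disease with functional impairment
ppo_non_tca_antidepressant	Central nervous system and eyes	cond:major_depression	non-tca antidepressants		PPO	persistent major depressive symptoms
ppo_achei_dementia	Central nervous system and eyes	cond:alzheimer_or_lewy_dementia	acetylcholinesterase inhibitors		PPO	mild-moderate Alzheimer or Lewy body dementia
ppo_glaucoma_topical	Central nervous system and eyes	cond:open_angle_glaucoma	topical prostaglandins|timolol		PPO	topical prostaglandin, prostamide or beta-blocker
ppo_ssri_anxiety	Central nervous system and eyes	cond:severe_anxiety	ssris|snris|pregabalin		PPO	SNRI or pregabalin if SSRI contraindicated
ppo_dopamine_agonist_rls	Central nervous system and eyes	cond:restless_legs_syndrome	ropinirole|pramipexole|rotigotine	cond:iron_deficiency ; cond:severe_renal_failure	PPO	once iron deficiency and severe renal failure excluded
ppo_ppi_gord	Gastrointestinal	cond:severe_gord	proton pump inhibitors		PPO	severe reflux disease or peptic stricture requiring dilatation
ppo_fibre_diverticulosis	Gastrointestinal	cond:diverticulosis & cond:constipation	fibre supplements		PPO
ppo_dmard_ra	Musculoskeletal system	cond:active_rheumatoid_arthritis	dmards		PPO	active disabling rheumatoid disease
ppo_bone_protection_steroids	Musculoskeletal system	med:systemic corticosteroids	bisphosphonates|vitamin d supplements|calcium supplements		PPO	bisphosphonate and vitamin D and calcium with long-term systemic corticosteroids; any one suffices to suppress the flag
ppo_vitd_calcium_osteoporosis	Musculoskeletal system	cond:osteoporosis ; cond:fragility_fracture ; meas:bmd_t_score<-2.5	vitamin d supplements|calcium supplements		PPO
ppo_antiresorptive_osteoporosis	Musculoskeletal system	cond:osteoporosis ; cond:fragility_fracture ; meas:bmd_t_score<-2.5	bisphosphonates|teriparatide|denosumab		PPO	where no contraindication exists
ppo_vitd_falls	Musculoskeletal system	cond:housebound ; cond:falls ; meas:bmd_t_score<-1.0	vitamin d supplements		PPO	housebound, falling, or osteopenia
ppo_xoi_gout	Musculoskeletal system	cond:recurrent_gout	xanthine oxidase inhibitors		PPO
ppo_folic_acid_methotrexate	Musculoskeletal system	med:methotrexate	folic acid		PPO
ppo_acei_arb_diabetic_nephropathy	Endocrine	cond:diabetes_mellitus & cond:diabetic_renal_disease	ace inhibitors|angiotensin receptor blockers		PPO	dipstick proteinuria or microalbuminuria > 30 mg/24 h
ppo_alpha1_prostatism	Urogenital	cond:symptomatic_prostatism	alpha-1 blockers		PPO	where prostatectomy not considered necessary
ppo_5ari_prostatism	Urogenital	cond:symptomatic_prostatism	5-alpha reductase inhibitors		PPO	where prostatectomy not considered necessary
ppo_vaginal_oestrogen	Urogenital	cond:atrophic_vaginitis	vaginal oestrogens		PPO	topical vaginal oestrogen or pessary
ppo_high_potency_opioid_pain	Opioids	cond:moderate_severe_pain	high-potency opioids		PPO	where paracetamol, NSAIDs or low-potency opioids inadequate
ppo_laxative_with_opioids	Opioids	med:opioids	laxatives		PPO	patients receiving opioids regularly
ppo_influenza_vaccine	Vaccines	vacc:influenza_past_year=false	influenza vaccine		PPO	seasonal trivalent influenza vaccine annually
ppo_pneumococcal_vaccine	Vaccines	age>=65 & vacc:pneumococcal_ever_after_65=false	pneumococcal vaccine		PPO	at least once after age 65
ppo_zoster_vaccine	Vaccines	age>=60 & vacc:zoster_ever=false	zoster vaccine		PPO	single dose, with or without prior herpes zoster episode
ppo_tdap_vaccine	Vaccines	age>=65 & vacc:tdap_ever=false	tdap vaccine		PPO	tetanus, diphtheria and pertussis vaccine at 65 or older
ppo_aspirin_af	Drugs that should not be restarted	cond:chronic_atrial_fibrillation	aspirin		NOT_PPO	aspirin 75-160 mg once daily where anticoagulants are contraindicated; adjudicated as not a PPO and never emitted as a recommendation
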