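item_id	category	proposed_round2	footnotes	printed_decision
aluminium_antacids	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
h2_receptor_antagonists	INDEPENDENT_PIM	0		POSITIVE
proton_pump_inhibitors	INDEPENDENT_PIM	0		POSITIVE
metoclopramide	INDEPENDENT_PIM	0		POSITIVE
atropine	INDEPENDENT_PIM	0		POSITIVE
belladonna_alkaloids	INDEPENDENT_PIM	0		POSITIVE
clidinium_chlordiazepoxide	INDEPENDENT_PIM	0		POSITIVE
dicyclomine	INDEPENDENT_PIM	0		POSITIVE
homatropine	INDEPENDENT_PIM	0		POSITIVE
viscous_paraffin	INDEPENDENT_PIM	0		POSITIVE
bisacodyl	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
cascara_sagrada	INDEPENDENT_PIM	0		POSITIVE
magnesium_oxide	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
polyethylene_glycol	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
metformin	INDEPENDENT_PIM	0		NEGATIVE
sulfonylureas_long_acting	INDEPENDENT_PIM	0		POSITIVE
pioglitazone	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
insulin_sliding_scale	INDEPENDENT_PIM	0		POSITIVE
acarbose	INDEPENDENT_PIM	0		NEGATIVE
sglt_inhibitors	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
dpp4_inhibitors	INDEPENDENT_PIM	0		NEGATIVE
aspirin	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
clopidogrel	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
dipyridamole	INDEPENDENT_PIM	0		POSITIVE
vitamin_k_antagonists	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
direct_thrombin_inhibitors	INDEPENDENT_PIM	0		POSITIVE
factor_xa_inhibitors	INDEPENDENT_PIM	0		POSITIVE
ticlopidine	INDEPENDENT_PIM	0		POSITIVE
prasugrel	INDEPENDENT_PIM	0		POSITIVE
enoxaparin	INDEPENDENT_PIM	0		NEGATIVE
heparin	INDEPENDENT_PIM	0		NEGATIVE
fondaparinux	INDEPENDENT_PIM	0		NEGATIVE
ticagrelor	INDEPENDENT_PIM	0		NEGATIVE
streptokinase	INDEPENDENT_PIM	0		NEGATIVE
oral_iron	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
digoxin	INDEPENDENT_PIM	0		POSITIVE
antiarrhythmics	INDEPENDENT_PIM	0		POSITIVE
ivabradine	INDEPENDENT_PIM	0		NEGATIVE
isosorbide_dinitrate	INDEPENDENT_PIM	0		NEGATIVE
isosorbide_mononitrate	INDEPENDENT_PIM	0		NEGATIVE
methyldopa	INDEPENDENT_PIM	0		POSITIVE
clonidine	INDEPENDENT_PIM	0		POSITIVE
moxonidine	INDEPENDENT_PIM	0		POSITIVE
doxazosin	INDEPENDENT_PIM	0		POSITIVE
prazosin	INDEPENDENT_PIM	0		POSITIVE
reserpine	INDEPENDENT_PIM	0		POSITIVE
loop_diuretics	INDEPENDENT_PIM	0		POSITIVE
thiazide_diuretics	INDEPENDENT_PIM	0		POSITIVE
spironolactone	INDEPENDENT_PIM	0		POSITIVE
pentoxifylline	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
non_selective_beta_blockers	INDEPENDENT_PIM	0		POSITIVE
non_dihydropyridine_ccb	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
dihydropyridine_ccb	INDEPENDENT_PIM	0		POSITIVE
felodipine	INDEPENDENT_PIM	0		NEGATIVE
ace_inhibitors	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
arbs	INDEPENDENT_PIM	0		NEGATIVE
sacubitril_valsartan	INDEPENDENT_PIM	0		NEGATIVE
statins	INDEPENDENT_PIM	0		NEGATIVE
gemfibrozil	INDEPENDENT_PIM	0		NEGATIVE
fenofibrate	INDEPENDENT_PIM	0		NEGATIVE
oral_oestrogens	INDEPENDENT_PIM	0		POSITIVE
androgens	INDEPENDENT_PIM	0		POSITIVE
megestrol	INDEPENDENT_PIM	0		POSITIVE
pde5_inhibitors	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
urinary_antimuscarinics	INDEPENDENT_PIM	0		POSITIVE
selective_alpha1_blockers	INDEPENDENT_PIM	0		POSITIVE
desmopressin	INDEPENDENT_PIM	0		POSITIVE
systemic_corticosteroids	INDEPENDENT_PIM	0		POSITIVE
levothyroxine	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
carbimazole	INDEPENDENT_PIM	0		NEGATIVE
nitrofurantoin	INDEPENDENT_PIM	0		POSITIVE
vancomycin	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
clindamycin	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
aminoglycosides	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
growth_hormone	INDEPENDENT_PIM	0		POSITIVE
monoclonal_antibodies	INDEPENDENT_PIM	0		POSITIVE
leflunomide	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
methotrexate	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
azathioprine	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
etanercept	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
non_cox2_nsaids	INDEPENDENT_PIM	0		POSITIVE
cox2_inhibitors	INDEPENDENT_PIM	0		POSITIVE
baclofen	INDEPENDENT_PIM	0		POSITIVE
orphenadrine	INDEPENDENT_PIM	0		POSITIVE
chlorzoxazone	INDEPENDENT_PIM	0		POSITIVE
colchicine	INDEPENDENT_PIM	0		POSITIVE
oral_bisphosphonates	INDEPENDENT_PIM	0	adjudicated	NEGATIVE
opioids	INDEPENDENT_PIM	0		POSITIVE
ergotamine_derivatives	INDEPENDENT_PIM	0		POSITIVE
paracetamol	INDEPENDENT_PIM	0		NEGATIVE
fentanyl_patch	INDEPENDENT_PIM	1	adjudicated	POSITIVE
barbiturates	INDEPENDENT_PIM	0		POSITIVE
phenytoin	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
lithium	INDEPENDENT_PIM	1	novel_vs_big4	POSITIVE
levetiracetam	INDEPENDENT_PIM	1	adjudicated	NEGATIVE
sodium_valproate	INDEPENDENT_PIM	1	adjudicated,novel_vs_big4	POSITIVE
carbamazepine	INDEPENDENT_PIM	0		NEGATIVE
trihexyphenidyl	INDEPENDENT_PIM	0		POSITIVE
biperiden	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
benzatropine	INDEPENDENT_PIM	0		POSITIVE
selegiline	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
levodopa_dopamine_agonists	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
barbiturates_hypnotic	INDEPENDENT_PIM	0		POSITIVE
atypical_antipsychotics	INDEPENDENT_PIM	0		POSITIVE
thioxanthenes	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
chloral_hydrate	INDEPENDENT_PIM	0		POSITIVE
benzodiazepines	INDEPENDENT_PIM	0		POSITIVE
phenothiazines	INDEPENDENT_PIM	0		POSITIVE
haloperidol	INDEPENDENT_PIM	0		POSITIVE
zopiclone	INDEPENDENT_PIM	0		POSITIVE
zolpidem	INDEPENDENT_PIM	0		POSITIVE
hydroxyzine	INDEPENDENT_PIM	0		POSITIVE
ssris	INDEPENDENT_PIM	0		POSITIVE
acetylcholinesterase_inhibitors	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
tricyclic_antidepressants	INDEPENDENT_PIM	0		POSITIVE
piracetam	INDEPENDENT_PIM	0		POSITIVE
methylphenidate	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
mirtazapine	INDEPENDENT_PIM	0		NEGATIVE
venlafaxine	INDEPENDENT_PIM	0		NEGATIVE
flunarizine	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
cinnarizine	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
hydroxychloroquine	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
xanthine_derivatives	INDEPENDENT_PIM	0		POSITIVE
antimuscarinic_bronchodilators	INDEPENDENT_PIM	0	novel_vs_big4	POSITIVE
first_generation_antihistamines	INDEPENDENT_PIM	0		POSITIVE
ppo_af_anticoagulant	PPO	0		POSITIVE
ppo_antiplatelet_vascular	PPO	0		POSITIVE
ppo_antihypertensive	PPO	0		POSITIVE
ppo_statin_vascular	PPO	0		POSITIVE
ppo_acei_hf_cad	PPO	0		POSITIVE
ppo_bb_ihd	PPO	0		POSITIVE
ppo_bb_hf	PPO	0		POSITIVE
ppo_inhaled_bronchodilator	PPO	0		POSITIVE
ppo_inhaled_corticosteroid	PPO	0		POSITIVE
ppo_home_oxygen	PPO	0		POSITIVE
ppo_levodopa_parkinson	PPO	0		POSITIVE
ppo_non_tca_antidepressant	PPO	0		POSITIVE
ppo_achei_dementia	PPO	0		POSITIVE
ppo_glaucoma_topical	PPO	0		POSITIVE
ppo_ssri_anxiety	PPO	0		POSITIVE
ppo_dopamine_agonist_rls	PPO	0		POSITIVE
ppo_ppi_gord	PPO	0		POSITIVE
ppo_fibre_diverticulosis	PPO	0		POSITIVE
ppo_dmard_ra	PPO	0		POSITIVE
ppo_bone_protection_steroids	PPO	0		POSITIVE
ppo_vitd_calcium_osteoporosis	PPO	0		POSITIVE
ppo_antiresorptive_osteoporosis	PPO	0		POSITIVE
ppo_vitd_falls	PPO	0		POSITIVE
ppo_xoi_gout	PPO	0		POSITIVE
ppo_folic_acid_methotrexate	PPO	0		POSITIVE
ppo_acei_arb_diabetic_nephropathy	PPO	0		POSITIVE
ppo_alpha1_prostatism	PPO	0		POSITIVE
ppo_5ari_prostatism	PPO	0		POSITIVE
ppo_vaginal_oestrogen	PPO	0		POSITIVE
ppo_high_potency_opioid_pain	PPO	0		POSITIVE
ppo_laxative_with_opioids	PPO	0		POSITIVE
ppo_influenza_vaccine	PPO	0		POSITIVE
ppo_pneumococcal_vaccine	PPO	0		POSITIVE
ppo_zoster_vaccine	PPO	1	proposed_round2	POSITIVE
ppo_tdap_vaccine	PPO	1	proposed_round2	POSITIVE
ppo_aspirin_af	PPO	0	adjudicated	NEGATIVE
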