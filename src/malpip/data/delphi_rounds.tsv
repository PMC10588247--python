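item_id	round	mean	ci_low	ci_high
aluminium_antacids	1	3.48	2.96	3.99
aluminium_antacids	2	2.62	2.23	3.01
h2_receptor_antagonists	1	2.76	2.21	3.32
h2_receptor_antagonists	2	2.19	1.88	2.50
proton_pump_inhibitors	1	2.62	2.00	3.24
proton_pump_inhibitors	2	2.19	1.74	2.63
metoclopramide	1	2.33	1.83	2.84
atropine	1	1.52	1.29	1.76
belladonna_alkaloids	1	1.71	1.38	2.04
clidinium_chlordiazepoxide	1	1.86	1.53	2.19
dicyclomine	1	2.00	1.71	2.29
homatropine	1	1.95	1.68	2.22
viscous_paraffin	1	3.10	2.49	3.70
viscous_paraffin	2	2.48	1.99	2.97
bisacodyl	1	3.10	2.47	3.72
bisacodyl	2	2.67	2.12	3.21
cascara_sagrada	1	2.95	2.62	3.29
cascara_sagrada	2	2.47	2.11	2.85
magnesium_oxide	1	3.14	2.75	3.53
magnesium_oxide	2	2.52	2.13	2.92
polyethylene_glycol	1	3.05	2.52	3.58
polyethylene_glycol	2	2.48	2.03	2.92
metformin	1	3.48	3.01	3.97
sulfonylureas_long_acting	1	2.14	1.60	2.69
pioglitazone	1	2.14	1.73	2.56
insulin_sliding_scale	1	2.81	2.24	3.38
insulin_sliding_scale	2	2.38	1.83	2.93
acarbose	1	3.57	3.12	4.01
sglt_inhibitors	1	3.29	2.82	3.74
sglt_inhibitors	2	2.81	2.34	3.28
dpp4_inhibitors	1	4.33	3.79	4.88
aspirin	1	2.86	2.37	3.34
aspirin	2	2.81	2.30	3.32
clopidogrel	1	2.95	2.42	3.48
clopidogrel	2	2.67	2.18	3.15
dipyridamole	1	2.52	2.01	3.04
dipyridamole	2	2.24	1.86	2.62
vitamin_k_antagonists	1	2.43	2.00	2.85
direct_thrombin_inhibitors	1	2.71	2.28	3.15
direct_thrombin_inhibitors	2	2.48	2.01	2.95
factor_xa_inhibitors	1	2.71	2.30	3.13
factor_xa_inhibitors	2	2.33	1.87	2.80
ticlopidine	1	2.43	1.98	2.87
prasugrel	1	2.33	1.89	2.77
enoxaparin	1	3.83	2.80	4.87
heparin	1	3.83	3.04	4.62
fondaparinux	1	4.00	3.34	4.66
ticagrelor	1	4.00	3.34	4.66
streptokinase	1	3.83	3.04	4.62
oral_iron	1	3.24	2.68	3.79
oral_iron	2	3.05	2.56	3.54
digoxin	1	2.05	1.65	2.44
antiarrhythmics	1	2.19	1.79	2.59
ivabradine	1	4.17	3.74	4.59
isosorbide_dinitrate	1	4.00	3.06	4.93
isosorbide_mononitrate	1	3.83	3.04	4.62
methyldopa	1	1.90	1.52	2.28
clonidine	1	2.00	1.59	2.40
moxonidine	1	2.52	2.07	2.97
doxazosin	1	2.29	1.78	2.79
prazosin	1	2.29	1.78	2.79
reserpine	1	1.90	1.56	2.25
loop_diuretics	1	2.33	1.83	2.84
thiazide_diuretics	1	2.29	1.83	2.74
spironolactone	1	2.38	1.92	2.85
pentoxifylline	1	2.81	2.26	3.36
pentoxifylline	2	2.62	2.13	3.11
non_selective_beta_blockers	1	2.33	1.94	2.72
non_dihydropyridine_ccb	1	2.43	1.98	2.87
dihydropyridine_ccb	1	2.43	1.91	2.94
felodipine	1	4.00	3.06	4.93
ace_inhibitors	1	3.48	2.95	4.00
ace_inhibitors	2	3.10	2.60	3.60
arbs	1	3.57	3.06	4.08
sacubitril_valsartan	1	3.83	3.04	4.62
statins	1	4.00	3.34	4.67
gemfibrozil	1	4.00	3.34	4.67
fenofibrate	1	4.17	3.74	4.59
oral_oestrogens	1	2.67	2.18	3.15
oral_oestrogens	2	2.33	1.89	2.77
androgens	1	2.48	2.05	2.90
megestrol	1	2.29	1.85	2.72
pde5_inhibitors	1	2.38	1.83	2.92
urinary_antimuscarinics	1	2.19	1.72	2.66
selective_alpha1_blockers	1	2.76	2.23	3.30
selective_alpha1_blockers	2	2.33	1.87	2.80
desmopressin	1	2.43	1.94	2.92
systemic_corticosteroids	1	2.19	1.79	2.59
levothyroxine	1	3.24	2.76	3.71
levothyroxine	2	2.86	2.40	3.32
carbimazole	1	4.17	3.74	4.59
nitrofurantoin	1	2.71	2.21	3.22
nitrofurantoin	2	2.48	2.05	2.90
vancomycin	1	2.81	2.36	3.26
vancomycin	2	2.43	1.92	2.94
clindamycin	1	2.86	2.40	3.32
clindamycin	2	2.52	2.13	2.92
aminoglycosides	1	2.57	2.15	2.99
growth_hormone	1	2.43	2.09	2.77
monoclonal_antibodies	1	3.00	2.62	3.38
monoclonal_antibodies	2	2.43	2.01	2.85
leflunomide	1	2.90	2.45	3.36
leflunomide	2	2.24	1.81	2.67
methotrexate	1	2.71	2.26	3.17
methotrexate	2	2.10	1.67	2.52
azathioprine	1	2.81	2.34	3.29
azathioprine	2	2.24	1.79	2.69
etanercept	1	2.90	2.46	3.36
etanercept	2	2.24	1.81	2.67
non_cox2_nsaids	1	1.81	1.39	2.23
cox2_inhibitors	1	2.24	1.83	2.64
baclofen	1	2.00	1.57	2.43
orphenadrine	1	1.81	1.50	2.11
chlorzoxazone	1	2.10	1.72	2.47
colchicine	1	2.90	2.37	3.44
colchicine	2	2.48	2.03	2.92
oral_bisphosphonates	1	3.38	2.99	3.77
oral_bisphosphonates	2	2.81	2.34	3.28
opioids	1	2.19	1.82	2.56
ergotamine_derivatives	1	2.24	1.81	2.67
paracetamol	1	4.29	4.03	4.54
fentanyl_patch	2	2.38	1.96	2.80
barbiturates	1	1.86	1.50	2.22
phenytoin	1	2.10	1.67	2.52
lithium	2	1.95	1.58	2.32
levetiracetam	2	3.14	2.60	3.69
sodium_valproate	2	2.33	1.89	2.77
carbamazepine	1	3.83	3.04	4.62
trihexyphenidyl	1	2.00	1.62	2.38
biperiden	1	2.24	1.89	2.59
benzatropine	1	2.10	1.74	2.45
selegiline	1	2.62	2.13	3.11
selegiline	2	2.48	2.11	2.85
levodopa_dopamine_agonists	1	3.10	2.62	3.57
levodopa_dopamine_agonists	2	2.48	2.03	2.92
barbiturates_hypnotic	1	1.81	1.47	2.15
atypical_antipsychotics	1	1.95	1.62	2.29
thioxanthenes	1	2.19	1.85	2.53
chloral_hydrate	1	2.19	1.79	2.59
benzodiazepines	1	1.67	1.40	1.92
phenothiazines	1	1.86	1.64	2.07
haloperidol	1	1.90	1.59	2.22
zopiclone	1	2.05	1.65	2.44
zolpidem	1	2.10	1.67	2.52
hydroxyzine	1	1.76	1.56	1.96
ssris	1	2.62	2.15	3.09
ssris	2	2.38	1.99	2.77
acetylcholinesterase_inhibitors	1	2.86	2.33	3.38
acetylcholinesterase_inhibitors	2	2.48	2.05	2.90
tricyclic_antidepressants	1	1.62	1.39	1.84
piracetam	1	2.90	2.43	3.38
piracetam	2	2.14	1.78	2.50
methylphenidate	1	2.33	1.92	2.75
mirtazapine	1	3.83	3.04	4.62
venlafaxine	1	3.83	3.04	4.62
flunarizine	1	2.76	2.24	3.28
flunarizine	2	2.29	1.93	2.64
cinnarizine	1	2.71	2.21	3.22
cinnarizine	2	2.43	2.03	2.82
hydroxychloroquine	1	2.17	1.38	2.96
xanthine_derivatives	1	2.24	1.81	2.67
antimuscarinic_bronchodilators	1	3.29	2.73	3.85
antimuscarinic_bronchodilators	2	2.48	2.05	2.90
first_generation_antihistamines	1	1.75	1.47	2.25
ppo_af_anticoagulant	1	2.10	1.64	2.55
ppo_antiplatelet_vascular	1	1.71	1.39	2.04
ppo_antihypertensive	1	2.24	1.89	2.59
ppo_statin_vascular	1	1.90	1.59	2.22
ppo_acei_hf_cad	1	1.67	1.40	1.93
ppo_bb_ihd	1	1.95	1.56	2.35
ppo_bb_hf	1	1.71	1.42	2.01
ppo_inhaled_bronchodilator	1	1.76	1.48	2.05
ppo_inhaled_corticosteroid	1	1.81	1.47	2.15
ppo_home_oxygen	1	2.10	1.71	2.47
ppo_levodopa_parkinson	1	2.00	1.54	2.46
ppo_non_tca_antidepressant	1	1.86	1.47	2.25
ppo_achei_dementia	1	2.05	1.63	2.47
ppo_glaucoma_topical	1	2.05	1.68	2.41
ppo_ssri_anxiety	1	1.95	1.58	2.32
ppo_dopamine_agonist_rls	1	2.43	2.03	2.82
ppo_ppi_gord	1	1.62	1.39	1.85
ppo_fibre_diverticulosis	1	2.10	1.78	2.41
ppo_dmard_ra	1	1.95	1.51	2.39
ppo_bone_protection_steroids	1	2.33	1.92	2.75
ppo_vitd_calcium_osteoporosis	1	1.76	1.52	2.01
ppo_antiresorptive_osteoporosis	1	2.05	1.65	2.44
ppo_vitd_falls	1	2.00	1.62	2.38
ppo_xoi_gout	1	1.95	1.68	2.22
ppo_folic_acid_methotrexate	1	1.67	1.40	1.93
ppo_acei_arb_diabetic_nephropathy	1	1.48	1.20	1.75
ppo_alpha1_prostatism	1	1.95	1.59	2.32
ppo_5ari_prostatism	1	2.00	1.68	2.32
ppo_vaginal_oestrogen	1	2.24	1.89	2.59
ppo_high_potency_opioid_pain	1	1.81	1.58	2.04
ppo_laxative_with_opioids	1	1.71	1.36	2.07
ppo_influenza_vaccine	1	1.57	1.30	1.84
ppo_pneumococcal_vaccine	1	1.62	1.31	1.92
ppo_zoster_vaccine	2	2.10	1.72	2.47
ppo_tdap_vaccine	2	2.14	1.81	2.47
ppo_aspirin_af	1	2.90	2.37	3.44
ppo_aspirin_af	2	3.10	2.56	3.63
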