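criterion_id	atc_group	target	target_kind	route	final_status	practice_statement
aluminium_antacids	A02	aluminium antacids	CLASS		NOT_PIM
h2_receptor_antagonists	A02	h2 receptor antagonists	CLASS		PIM	S2:h2_receptor_antagonists
proton_pump_inhibitors	A02	proton pump inhibitors	CLASS		PIM	S2:proton_pump_inhibitors
metoclopramide	A02	metoclopramide	DRUG		PIM	S2:metoclopramide
atropine	A02	atropine	DRUG		PIM	S2:atropine
belladonna_alkaloids	A02	belladonna alkaloids	CLASS		PIM	S2:belladonna_alkaloids
clidinium_chlordiazepoxide	A02	clidinium-chlordiazepoxide	DRUG		PIM	S2:clidinium_chlordiazepoxide
dicyclomine	A02	dicyclomine	DRUG		PIM	S2:dicyclomine
homatropine	A02	homatropine	DRUG		PIM	S2:homatropine
viscous_paraffin	A06	viscous paraffin	DRUG		PIM	S2:viscous_paraffin
bisacodyl	A06	bisacodyl	DRUG		NOT_PIM
cascara_sagrada	A06	cascara sagrada	DRUG		PIM	S2:cascara_sagrada
magnesium_oxide	A06	magnesium oxide	DRUG		PIM	S2:magnesium_oxide
polyethylene_glycol	A06	polyethylene glycol	DRUG		PIM	S2:polyethylene_glycol
metformin	A10	metformin	DRUG		NOT_PIM
sulfonylureas_long_acting	A10	long-acting sulfonylureas	CLASS		PIM	S2:sulfonylureas_long_acting
pioglitazone	A10	pioglitazone	DRUG		PIM	S2:pioglitazone
insulin_sliding_scale	A10	insulin sliding scale	DRUG		PIM	S2:insulin_sliding_scale
acarbose	A10	acarbose	DRUG		NOT_PIM
sglt_inhibitors	A10	sglt inhibitors	CLASS		NOT_PIM
dpp4_inhibitors	A10	dpp4 inhibitors	CLASS		NOT_PIM
aspirin	B01	aspirin	DRUG		NOT_PIM
clopidogrel	B01	clopidogrel	DRUG		NOT_PIM
dipyridamole	B01	dipyridamole	DRUG		PIM	S2:dipyridamole
vitamin_k_antagonists	B01	vitamin k antagonists	CLASS		PIM	S2:vitamin_k_antagonists
direct_thrombin_inhibitors	B01	direct thrombin inhibitors	CLASS		PIM	S2:direct_thrombin_inhibitors
factor_xa_inhibitors	B01	factor xa inhibitors	CLASS		PIM	S2:factor_xa_inhibitors
ticlopidine	B01	ticlopidine	DRUG		PIM	S2:ticlopidine
prasugrel	B01	prasugrel	DRUG		PIM	S2:prasugrel
enoxaparin	B01	enoxaparin	DRUG		NOT_PIM
heparin	B01	heparin	DRUG		NOT_PIM
fondaparinux	B01	fondaparinux	DRUG		NOT_PIM
ticagrelor	B01	ticagrelor	DRUG		NOT_PIM
streptokinase	B01	streptokinase	DRUG		NOT_PIM
oral_iron	B03	oral iron	CLASS	oral	NOT_PIM
digoxin	C01	digoxin	DRUG		PIM	S2:digoxin
antiarrhythmics	C01	antiarrhythmics	CLASS		PIM	S2:antiarrhythmics
ivabradine	C01	ivabradine	DRUG		NOT_PIM
isosorbide_dinitrate	C01	isosorbide dinitrate	DRUG		NOT_PIM
isosorbide_mononitrate	C01	isosorbide mononitrate	DRUG		NOT_PIM
methyldopa	C02	methyldopa	DRUG		PIM	S2:methyldopa
clonidine	C02	clonidine	DRUG		PIM	S2:clonidine
moxonidine	C02	moxonidine	DRUG		PIM	S2:moxonidine
doxazosin	C02	doxazosin	DRUG		PIM	S2:doxazosin
prazosin	C02	prazosin	DRUG		PIM	S2:prazosin
reserpine	C02	reserpine	DRUG		PIM	S2:reserpine
loop_diuretics	C03	loop diuretics	CLASS		PIM	S2:loop_diuretics
thiazide_diuretics	C03	thiazide diuretics	CLASS		PIM	S2:thiazide_diuretics
spironolactone	C03	spironolactone	DRUG		PIM	S2:spironolactone
pentoxifylline	C04	pentoxifylline	DRUG		NOT_PIM
non_selective_beta_blockers	C07	non-selective beta blockers	CLASS		PIM	S2:non_selective_beta_blockers
non_dihydropyridine_ccb	C08	non-dihydropyridine calcium channel blockers	CLASS		PIM	S2:non_dihydropyridine_ccb
dihydropyridine_ccb	C08	dihydropyridine calcium channel blockers	CLASS		PIM	S2:dihydropyridine_ccb
felodipine	C08	felodipine	DRUG		NOT_PIM
ace_inhibitors	C09	ace inhibitors	CLASS		NOT_PIM
arbs	C09	angiotensin receptor blockers	CLASS		NOT_PIM
sacubitril_valsartan	C09	sacubitril-valsartan	DRUG		NOT_PIM
statins	C10	statins	CLASS		NOT_PIM
gemfibrozil	C10	gemfibrozil	DRUG		NOT_PIM
fenofibrate	C10	fenofibrate	DRUG		NOT_PIM
oral_oestrogens	G03	oral oestrogens	CLASS	oral	PIM	S2:oral_oestrogens
androgens	G03	androgens	CLASS		PIM	S2:androgens
megestrol	G03	megestrol	DRUG		PIM	S2:megestrol
pde5_inhibitors	G04	phosphodiesterase-5 inhibitors	CLASS		PIM	S2:pde5_inhibitors
urinary_antimuscarinics	G04	urological antimuscarinics	CLASS		PIM	S2:urinary_antimuscarinics
selective_alpha1_blockers	G04	selective alpha-1 blockers	CLASS		PIM	S2:selective_alpha1_blockers
desmopressin	H01	desmopressin	DRUG		PIM	S2:desmopressin
systemic_corticosteroids	H02	systemic corticosteroids	CLASS		PIM	S2:systemic_corticosteroids
levothyroxine	H03	levothyroxine	DRUG		NOT_PIM
carbimazole	H03	carbimazole	DRUG		NOT_PIM
nitrofurantoin	J01	nitrofurantoin	DRUG		PIM	S2:nitrofurantoin
vancomycin	J01	vancomycin	DRUG		PIM	S2:vancomycin
clindamycin	J01	clindamycin	DRUG		PIM	S2:clindamycin
aminoglycosides	J01	aminoglycosides	CLASS		PIM	S2:aminoglycosides
growth_hormone	L01	growth hormone	DRUG		PIM	S2:growth_hormone
monoclonal_antibodies	L01	monoclonal antibodies	CLASS		PIM	S2:monoclonal_antibodies
leflunomide	L04	leflunomide	DRUG		PIM	S2:leflunomide
methotrexate	L04	methotrexate	DRUG		PIM	S2:methotrexate
azathioprine	L04	azathioprine	DRUG		PIM	S2:azathioprine
etanercept	L04	etanercept	DRUG		PIM	S2:etanercept
non_cox2_nsaids	M01	non-cox-2 selective nsaids	CLASS		PIM	S2:non_cox2_nsaids
cox2_inhibitors	M01	cox-2 selective inhibitors	CLASS		PIM	S2:cox2_inhibitors
baclofen	M03	baclofen	DRUG		PIM	S2:baclofen
orphenadrine	M03	orphenadrine	DRUG		PIM	S2:orphenadrine
chlorzoxazone	M03	chlorzoxazone	DRUG		PIM	S2:chlorzoxazone
colchicine	M04	colchicine	DRUG		PIM	S2:colchicine
oral_bisphosphonates	M05	oral bisphosphonates	CLASS	oral	NOT_PIM
opioids	N02	opioids	CLASS		PIM	S2:opioids
ergotamine_derivatives	N02	ergotamine derivatives	CLASS		PIM	S2:ergotamine_derivatives
paracetamol	N02	paracetamol	DRUG		NOT_PIM
fentanyl_patch	N02	fentanyl	DRUG	transdermal	PIM	S2:fentanyl_patch
barbiturates	N03	barbiturates	CLASS		PIM	S2:barbiturates
phenytoin	N03	phenytoin	DRUG		PIM	S2:phenytoin
lithium	N03	lithium	DRUG		PIM	S2:lithium
levetiracetam	N03	levetiracetam	DRUG		NOT_PIM
sodium_valproate	N03	sodium valproate	DRUG		PIM	S2:sodium_valproate
carbamazepine	N03	carbamazepine	DRUG		NOT_PIM
trihexyphenidyl	N04	trihexyphenidyl	DRUG		PIM	S2:trihexyphenidyl
biperiden	N04	biperiden	DRUG		PIM	S2:biperiden
benzatropine	N04	benzatropine	DRUG		PIM	S2:benzatropine
selegiline	N04	selegiline	DRUG		PIM	S2:selegiline
levodopa_dopamine_agonists	N04	levodopa and dopamine agonists	CLASS		PIM	S2:levodopa_dopamine_agonists
barbiturates_hypnotic	N05	barbiturates with hypnotic properties	CLASS		PIM	S2:barbiturates_hypnotic
atypical_antipsychotics	N05	atypical antipsychotics	CLASS		PIM	S2:atypical_antipsychotics
thioxanthenes	N05	thioxanthenes	CLASS		PIM	S2:thioxanthenes
chloral_hydrate	N05	chloral hydrate	DRUG		PIM	S2:chloral_hydrate
benzodiazepines	N05	benzodiazepines	CLASS		PIM	S2:benzodiazepines
phenothiazines	N05	phenothiazines	CLASS		PIM	S2:phenothiazines
haloperidol	N05	haloperidol	DRUG		PIM	S2:haloperidol
zopiclone	N05	zopiclone	DRUG		PIM	S2:zopiclone
zolpidem	N05	zolpidem	DRUG		PIM	S2:zolpidem
hydroxyzine	N05	hydroxyzine	DRUG		PIM	S2:hydroxyzine
ssris	N06	ssris	CLASS		PIM	S2:ssris
acetylcholinesterase_inhibitors	N06	acetylcholinesterase inhibitors	CLASS		PIM	S2:acetylcholinesterase_inhibitors
tricyclic_antidepressants	N06	tricyclic antidepressants	CLASS		PIM	S2:tricyclic_antidepressants
piracetam	N06	piracetam	DRUG		PIM	S2:piracetam
methylphenidate	N06	methylphenidate	DRUG		PIM	S2:methylphenidate
mirtazapine	N06	mirtazapine	DRUG		NOT_PIM
venlafaxine	N06	venlafaxine	DRUG		NOT_PIM
flunarizine	N07	flunarizine	DRUG		PIM	S2:flunarizine
cinnarizine	N07	cinnarizine	DRUG		PIM	S2:cinnarizine
hydroxychloroquine	P01	hydroxychloroquine	DRUG		PIM	S2:hydroxychloroquine
xanthine_derivatives	R03	xanthine derivatives	CLASS		PIM	S2:xanthine_derivatives
antimuscarinic_bronchodilators	R03	antimuscarinic bronchodilators	CLASS		PIM	S2:antimuscarinic_bronchodilators
first_generation_antihistamines	R06	first generation antihistamines	CLASS		PIM	S2:first_generation_antihistamines
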