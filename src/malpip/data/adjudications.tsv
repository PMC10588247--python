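item_id	panel_size	votes_positive	outcome
aluminium_antacids	6		NEGATIVE
bisacodyl	6		NEGATIVE
sglt_inhibitors	6		NEGATIVE
aspirin	6		NEGATIVE
clopidogrel	6		NEGATIVE
oral_iron	6		NEGATIVE
pentoxifylline	6		NEGATIVE
ace_inhibitors	6		NEGATIVE
levothyroxine	6		NEGATIVE
oral_bisphosphonates	6		NEGATIVE
levetiracetam	6		NEGATIVE
ppo_aspirin_af	6		NEGATIVE
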