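item	fatigue	respiratory	psychological	hormonal	chemo_toxicity	weight_gain	gastrointestinal	epithelial
lack_of_energy	0.880	0.000	0.000	0.000	0.000	0.000	0.000	0.000
difficulty_sleeping	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
pain	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
feeling_drowsy	0.621	0.000	0.000	0.000	0.000	0.000	0.000	0.000
hair_loss	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.468
difficulty_concentrating	0.401	0.000	0.436	0.000	0.000	0.000	0.000	0.000
worrying	0.000	0.000	0.792	0.000	0.000	0.000	0.000	0.000
nausea	0.430	0.000	0.000	0.000	0.000	0.000	0.000	0.000
feeling_sad	0.000	0.000	0.755	0.000	0.000	0.000	0.000	0.000
numbness_tingling	0.000	0.000	0.000	0.000	0.466	0.000	0.000	0.000
food_taste_change	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.709
feeling_irritable	0.000	0.000	0.512	0.000	0.000	0.000	0.000	0.000
dry_mouth	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
constipation	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
lack_of_appetite	0.000	0.000	0.000	0.000	0.000	0.000	0.537	0.000
hot_flashes	0.000	0.000	0.000	0.807	0.000	0.000	0.000	0.000
skin_changes	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.494
feeling_nervous	0.000	0.000	0.623	0.000	0.000	0.000	0.000	0.000
dont_look_like_myself	0.000	0.000	0.520	0.000	0.000	0.000	0.000	0.000
sweats	0.000	0.000	0.000	0.788	0.000	0.000	0.000	0.000
sexual_problems	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
feeling_bloated	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
dizziness	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
cough	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
diarrhea	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
weight_gain	0.000	0.000	0.000	0.000	0.000	0.942	0.000	0.000
increased_appetite	0.000	0.000	0.000	0.000	0.000	0.840	0.000	0.000
shortness_of_breath	0.000	0.824	0.000	0.000	0.000	0.000	0.000	0.000
itching	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
weight_loss	0.000	0.000	0.000	0.000	0.000	0.000	0.548	0.000
abdominal_cramps	0.000	0.000	0.000	0.000	0.481	0.000	0.000	0.000
mouth_sores	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.437
difficulty_breathing	0.000	1.049	0.000	0.000	0.000	0.000	0.000	0.000
chest_tightness	0.000	0.611	0.000	0.000	0.000	0.000	0.000	0.000
difficulty_swallowing	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.464
vomiting	0.000	0.000	0.000	0.000	0.000	0.000	0.526	0.000
swelling_arms_legs	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
urination_problems	0.000	0.000	0.000	0.000	0.621	0.000	0.000	0.000
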