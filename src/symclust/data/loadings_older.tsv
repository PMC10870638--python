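item	fatigue	respiratory	psychological	hormonal	chemo_toxicity	weight_gain	gastrointestinal	epithelial
lack_of_energy	0.743	0.000	0.000	0.000	0.000	0.000	0.000	0.000
difficulty_sleeping	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
pain	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
feeling_drowsy	0.463	0.000	0.000	0.000	0.000	0.000	0.000	0.000
hair_loss	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.540
difficulty_concentrating	0.541	0.000	0.437	0.000	0.000	0.000	0.000	0.000
worrying	0.000	0.000	0.812	0.000	0.000	0.000	0.000	0.000
nausea	0.000	0.000	0.000	0.000	0.000	0.000	0.704	0.000
feeling_sad	0.000	0.000	0.866	0.000	0.000	0.000	0.000	0.000
numbness_tingling	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
food_taste_change	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.612
feeling_irritable	0.000	0.000	0.628	0.000	0.000	0.000	0.000	0.000
dry_mouth	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
constipation	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
lack_of_appetite	0.000	0.000	0.000	0.000	0.000	0.000	0.478	0.000
hot_flashes	0.000	0.000	0.000	0.728	0.000	0.000	0.000	0.000
skin_changes	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.679
feeling_nervous	0.000	0.000	0.678	0.000	0.000	0.000	0.000	0.000
dont_look_like_myself	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.522
sweats	0.000	0.000	0.000	0.783	0.000	0.000	0.000	0.000
sexual_problems	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
feeling_bloated	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
dizziness	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.479
cough	0.000	0.403	0.000	0.000	0.000	0.000	0.000	0.000
diarrhea	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
weight_gain	0.000	0.000	0.000	0.000	0.000	0.902	0.000	0.000
increased_appetite	0.000	0.000	0.000	0.000	0.000	0.802	0.000	0.000
shortness_of_breath	0.000	0.878	0.000	0.000	0.000	0.000	0.000	0.000
itching	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
weight_loss	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
abdominal_cramps	0.000	0.000	0.000	0.000	0.489	0.000	0.000	0.000
mouth_sores	0.000	0.000	0.000	0.000	0.476	0.000	0.000	0.000
difficulty_breathing	0.000	0.965	0.000	0.000	0.000	0.000	0.000	0.000
chest_tightness	0.000	0.676	0.000	0.000	0.000	0.000	0.000	0.000
difficulty_swallowing	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.494
vomiting	0.000	0.000	0.000	0.000	0.000	0.000	0.926	0.000
swelling_arms_legs	0.000	0.000	0.000	0.000	0.000	0.000	0.000	0.000
urination_problems	0.000	0.402	0.000	0.000	0.418	0.000	0.000	0.000
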