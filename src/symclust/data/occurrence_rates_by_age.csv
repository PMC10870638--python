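code,pct_younger,pct_older
lack_of_energy,84.5,81.6
difficulty_sleeping,72.6,64.8
pain,63.3,56.9
feeling_drowsy,60.4,60.1
hair_loss,57.5,51.4
difficulty_concentrating,57.1,45.6
worrying,57.0,46.1
nausea,52.7,41.1
feeling_sad,51.4,39.6
numbness_tingling,51.1,53.6
food_taste_change,50.7,47.7
feeling_irritable,47.5,33.7
dry_mouth,45.2,45.6
constipation,45.1,41.6
lack_of_appetite,42.9,39.4
hot_flashes,42.2,19.2
skin_changes,41.9,29.4
feeling_nervous,41.8,33.4
dont_look_like_myself,40.5,34.6
sweats,39.0,21.7
sexual_problems,36.8,21.4
feeling_bloated,36.0,29.5
dizziness,31.4,31.2
cough,30.5,35.1
diarrhea,30.3,28.7
weight_gain,27.8,22.4
increased_appetite,26.8,24.7
shortness_of_breath,26.3,27.5
itching,25.2,24.4
weight_loss,24.7,25.9
abdominal_cramps,24.1,20.5
mouth_sores,22.5,19.0
difficulty_breathing,19.5,20.5
chest_tightness,19.0,16.4
difficulty_swallowing,15.3,11.9
vomiting,14.5,9.7
swelling_arms_legs,12.9,16.7
urination_problems,11.6,17.0
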