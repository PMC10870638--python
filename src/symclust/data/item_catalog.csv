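code,label
lack_of_energy,Lack of energy
difficulty_sleeping,Difficulty sleeping
pain,Pain
feeling_drowsy,Feeling drowsy
hair_loss,Hair loss
difficulty_concentrating,Difficulty concentrating
worrying,Worrying
nausea,Nausea
feeling_sad,Feeling sad
numbness_tingling,Numbness/tingling in hands/feet
food_taste_change,Change in the way food tastes
feeling_irritable,Feeling irritable
dry_mouth,Dry mouth
constipation,Constipation
lack_of_appetite,Lack of appetite
hot_flashes,Hot flashes
skin_changes,Skin changes
feeling_nervous,Feeling nervous
dont_look_like_myself,I don't look like myself
sweats,Sweats
sexual_problems,Problems with sexual interest or activity
feeling_bloated,Feeling bloated
dizziness,Dizziness
cough,Cough
diarrhea,Diarrhea
weight_gain,Weight gain
increased_appetite,Increased appetite
shortness_of_breath,Shortness of breath
itching,Itching
weight_loss,Weight loss
abdominal_cramps,Abdominal cramps
mouth_sores,Mouth sores
difficulty_breathing,Difficulty breathing
chest_tightness,Chest tightness
difficulty_swallowing,Difficulty swallowing
vomiting,Vomiting
swelling_arms_legs,Swelling of arms or legs
urination_problems,Problems with urination
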