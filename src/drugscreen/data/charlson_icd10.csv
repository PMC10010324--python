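icd10_prefix,entity,weight
I21,myocardial_infarction,1
I22,myocardial_infarction,1
I252,myocardial_infarction,1
I50,heart_failure,1
I11,heart_failure,1
I42,heart_failure,1
I43,heart_failure,1
I70,peripheral_vascular,1
I71,peripheral_vascular,1
I73,peripheral_vascular,1
G45,cerebrovascular,1
G46,cerebrovascular,1
I60,cerebrovascular,1
I61,cerebrovascular,1
I62,cerebrovascular,1
I63,cerebrovascular,1
I64,cerebrovascular,1
I65,cerebrovascular,1
I66,cerebrovascular,1
I67,cerebrovascular,1
I68,cerebrovascular,1
I69,cerebrovascular,1
F00,dementia,1
F01,dementia,1
F02,dementia,1
F03,dementia,1
G30,dementia,1
J40,chronic_pulmonary,1
J41,chronic_pulmonary,1
J42,chronic_pulmonary,1
J43,chronic_pulmonary,1
J44,chronic_pulmonary,1
J45,chronic_pulmonary,1
J46,chronic_pulmonary,1
J47,chronic_pulmonary,1
J60,chronic_pulmonary,1
J61,chronic_pulmonary,1
J62,chronic_pulmonary,1
J63,chronic_pulmonary,1
J64,chronic_pulmonary,1
J65,chronic_pulmonary,1
J66,chronic_pulmonary,1
J67,chronic_pulmonary,1
M05,rheumatic_disease,1
M06,rheumatic_disease,1
M32,rheumatic_disease,1
M33,rheumatic_disease,1
M34,rheumatic_disease,1
K25,peptic_ulcer,1
K26,peptic_ulcer,1
K27,peptic_ulcer,1
K28,peptic_ulcer,1
B18,mild_liver_disease,1
K70,mild_liver_disease,1
K73,mild_liver_disease,1
K74,mild_liver_disease,1
E10,diabetes_uncomplicated,1
E11,diabetes_uncomplicated,1
E13,diabetes_uncomplicated,1
E14,diabetes_uncomplicated,1
E102,diabetes_complicated,2
E103,diabetes_complicated,2
E104,diabetes_complicated,2
E105,diabetes_complicated,2
E107,diabetes_complicated,2
E112,diabetes_complicated,2
E113,diabetes_complicated,2
E114,diabetes_complicated,2
E115,diabetes_complicated,2
E117,diabetes_complicated,2
E132,diabetes_complicated,2
E133,diabetes_complicated,2
E134,diabetes_complicated,2
E135,diabetes_complicated,2
E137,diabetes_complicated,2
E142,diabetes_complicated,2
E143,diabetes_complicated,2
E144,diabetes_complicated,2
E145,diabetes_complicated,2
E147,diabetes_complicated,2
G81,hemiplegia,2
G82,hemiplegia,2
N18,renal_disease,2
N19,renal_disease,2
Z49,renal_disease,2
I85,severe_liver_disease,3
K704,severe_liver_disease,3
K72,severe_liver_disease,3
K766,severe_liver_disease,3
K767,severe_liver_disease,3
B20,hiv,6
B21,hiv,6
B22,hiv,6
B24,hiv,6
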