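code,dictionary,term_text
G340.11,READ,Triple vessel disease of the heart
G20..00,READ,Essential hypertension
B46..00,READ,Malignant neoplasm of prostate
R059.00,READ,[D]Sinus bradycardia
P769000,READ,Renal artery stenosis
G581.00,READ,Left ventricular failure
G581000,READ,Acute left ventricular failure
8H3Z.00,READ,Other hospital admission NOS
14A4.00,READ,H/O: myocardial infarct
G30..00,READ,Acute myocardial infarction
213100,READ,[D]Found Dead
42J..00,READ,Neutrophil count
9D2..00,READ,MED5 - doctor's special statement
22J..12,READ,Death
55...11,READ,Angiography - CVS
55...12,READ,Angiogram
32...00,READ,Electrocardiography
5853.11,READ,Echocardiogram
33B9500,READ,Exercise tolerance test abnormal
R065600,READ,[D]Chest discomfort
E2B..00,READ,Depressive disorder NEC
B723z00,READ,Benign neoplasm of bronchus or lung NOS
T503.00,READ,Aircraft crash while landing
K510000,READ,Cystocele without uterine prolapse
G573000,READ,Atrial fibrillation
G66..00,READ,Stroke unspecified
G580.00,READ,Congestive cardiac failure
A38..00,READ,Septicaemia
B22z.00,READ,Lung cancer
H3z..00,READ,Chronic obstructive pulmonary disease
G575.00,READ,Cardiac arrest
G801.00,READ,Deep vein thrombosis
G6...00,READ,Cerebrovascular disease
G3...00,READ,Ischaemic heart disease
Eu02z00,READ,[X] Unspecified dementia
B902.00,READ,[M]Carcinomatosis
H262.00,READ,Aspiration pneumonia
H260.00,READ,Lobar pneumonia
G674.00,READ,Cerebral infarction
B576.00,READ,Secondary malignant neoplasm of liver
T4002,OXMIS,SUDDEN DEATH
486B,OXMIS,BRONCHOPNEUMONIA
486,OXMIS,PNEUMONIA
7969U,OXMIS,UNKNOWN CAUSE
4120AT,OXMIS,CORONARY ARTERY ATHEROMA
199C,OXMIS,CARCINOMA
401,OXMIS,HYPERTENSION
6233C,OXMIS,CYSTOCELE
N821,OXMIS,FRACTURE FEMUR
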