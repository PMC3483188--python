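source,replacement,penalty
ca,malignant neoplasm,0.10
mi,myocardial infarction,0.10
admitted,hospital admission,0.10
admission,hospital admission,0.10
infarct,infarction,0.10
cva,stroke,0.10
dvt,deep vein thrombosis,0.10
copd,chronic obstructive pulmonary disease,0.10
ccf,congestive cardiac failure,0.10
ihd,ischaemic heart disease,0.10
af,atrial fibrillation,0.10
fractured,fracture,0.10
#,fracture,0.10
tumour,neoplasm,0.10
cancer,malignant neoplasm,0.10
sepsis,septicaemia,0.10
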