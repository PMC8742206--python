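short	long
pt	patient
sob	shortness of breath
copd	chronic obstructive airway disease
uti	urinary tract infection
lrti	lower respiratory tract infection
mi	myocardial infarction
dvt	deep vein thrombosis
pe	pulmonary embolism
af	atrial fibrillation
hb	hemoglobin
bp	blood pressure
obs	observations
hx	history
rx	treatment
abx	antibiotics
temp	temperature
cxr	chest x-ray
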