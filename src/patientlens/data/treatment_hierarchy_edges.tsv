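oxygen_therapy	therapy
antifibrotic_therapy	therapy
pulmonary_rehabilitation	therapy
physiotherapy	therapy
lung_transplant	medical_procedure
mechanical_ventilation	medical_procedure
spirometry	medical_test
chest_xray	medical_test
ct_scan	medical_test
medical_test	medical_procedure
biopsy	invasive_test
invasive_test	medical_procedure
six_minute_walk	health_assessment
health_assessment	medical_procedure
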