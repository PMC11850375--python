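therapy	therapy
medical_procedure	medical procedure
oxygen_therapy	oxygen therapy
antifibrotic_therapy	antifibrotic therapy
pulmonary_rehabilitation	pulmonary rehabilitation
physiotherapy	physiotherapy
lung_transplant	lung transplant
mechanical_ventilation	mechanical ventilation
spirometry	spirometry
chest_xray	chest x-ray
ct_scan	CT scan
medical_test	medical test
biopsy	biopsy
invasive_test	invasive test
six_minute_walk	six minute walk test
health_assessment	health assessment
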