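idiopathic pulmonary fibrosis	DI	D054990	mesh_fixture
pulmonary fibrosis	DI	D011658	mesh_fixture
IPF	DI	D054990	mesh_fixture
idiopathic lung fibrosis	DI	D054990	mesh_fixture
COPD	DI	D029424	mesh_fixture
emphysema	DI	D004646	mesh_fixture
pneumonia	DI	D011014	mesh_fixture
rheumatoid arthritis	DI	D001172	mesh_fixture
lung cancer	DI	D008175	mesh_fixture
asthma	DI	D001249	mesh_fixture
cough	DI	D003371	mesh_fixture
cough	SY	D003371	mesh_fixture
shortness of breath	SY	D004417	mesh_fixture
breathlessness	SY	D004417	mesh_fixture
fatigue	DI	D005221	mesh_fixture
fatigue	SY	D005221	mesh_fixture
clubbing	SY	D010015	mesh_fixture
chest pain	SY	D002637	mesh_fixture
weight loss	SY	D015431	mesh_fixture
dizziness	SY	D004244	mesh_fixture
fever	SY	D005334	mesh_fixture
wheezing	SY	D012135	mesh_fixture
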