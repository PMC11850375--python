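lung transplant	TR	Q1759570	wikidata_fixture
oxygen therapy	TR	Q1325527	wikidata_fixture
pulmonary rehabilitation	TR	Q7259945	wikidata_fixture
physiotherapy	TR	Q186005	wikidata_fixture
antifibrotic therapy	TR	Q4773895	wikidata_fixture
mechanical ventilation	TR	Q1570905	wikidata_fixture
supplemental oxygen	TR	Q1325528	wikidata_fixture
breathing exercises	TR	Q4959461	wikidata_fixture
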