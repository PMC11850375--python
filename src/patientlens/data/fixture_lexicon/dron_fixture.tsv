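pirfenidone	DR	DRON:00018575	dron_fixture
nintedanib	DR	DRON:00027994	dron_fixture
prednisone	DR	DRON:00018557	dron_fixture
azathioprine	DR	DRON:00018003	dron_fixture
sildenafil	DR	DRON:00018992	dron_fixture
morphine	DR	DRON:00018516	dron_fixture
paracetamol	DR	DRON:00018584	dron_fixture
ibuprofen	DR	DRON:00018292	dron_fixture
application	DR	DRON:00000099	dron_fixture
group	DR	DRON:00000098	dron_fixture
role	DR	DRON:00000097	dron_fixture
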