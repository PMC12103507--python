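term	identifier	synonyms
inflammatory bowel disease	DOID:0050589	ibd
Crohn's disease	DOID:8778	crohn disease|crohns disease
ulcerative colitis	DOID:8577	uc
diabetes mellitus	DOID:9351	diabetes
type 2 diabetes mellitus	DOID:9352	type 2 diabetes|t2d
obesity	DOID:9970	obese
Alzheimer's disease	DOID:10652	alzheimer disease
colorectal cancer	DOID:9256	colorectal carcinoma
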