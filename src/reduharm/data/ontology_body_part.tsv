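term	identifier	synonyms
urine	UBERON:0001088	urine sample
blood plasma	UBERON:0001969	plasma|edta plasma|heparin plasma
blood serum	UBERON:0001977	serum
blood	UBERON:0000178	whole blood
heart	UBERON:0000948	cardiac tissue
myocardium	UBERON:0002349	heart muscle|myocardium tissue
liver	UBERON:0002107	hepatic tissue
brain	UBERON:0000955	whole brain
kidney	UBERON:0002113	renal tissue
lung	UBERON:0002048	pulmonary tissue
feces	UBERON:0001988	stool|faeces|fecal sample
saliva	UBERON:0001836	oral fluid
skin of body	UBERON:0002097	skin
colon	UBERON:0001155	large intestine mucosa
muscle tissue	UBERON:0002385	skeletal muscle
cerebrospinal fluid	UBERON:0001359	csf
adipose tissue	UBERON:0001013	fat tissue
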