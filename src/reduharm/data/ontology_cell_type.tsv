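term	identifier	synonyms
T cell	CL:0000084	t-cells|t cells|t lymphocyte|t-cell
B cell	CL:0000236	b-cells|b cells|b lymphocyte
macrophage	CL:0000235	macrophages
hepatocyte	CL:0000182	hepatocytes
fibroblast	CL:0000057	fibroblasts
neuron	CL:0000540	neurons|nerve cell
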