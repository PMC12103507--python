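term	identifier	synonyms
leaf	PO:0025034	leaves|leaf tissue
root	PO:0009005	roots|root tissue
stem	PO:0009047	shoot axis
seed	PO:0009010	seeds
fruit	PO:0009001	fruits
flower	PO:0009046	flowers
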