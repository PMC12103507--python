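term	identifier	synonyms
Q Exactive	MS:1001911	q exactive orbitrap|qexactive|thermo q exactive
Q Exactive HF	MS:1002523	q exactive hf-x
Orbitrap Fusion Lumos	MS:1002732	fusion lumos
Orbitrap Exploris 480	MS:1003028	exploris 480
timsTOF Pro	MS:1003005	bruker timstof pro
maXis II	MS:1003004	bruker maxis ii
TripleTOF 6600	MS:1002533	sciex tripletof 6600
6550 iFunnel Q-TOF	MS:1002789	agilent 6550|6550 qtof
LTQ Orbitrap XL	MS:1000556	orbitrap xl
Xevo G2-XS QTof	MS:1002727	waters xevo g2-xs
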