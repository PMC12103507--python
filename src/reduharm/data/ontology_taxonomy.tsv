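term	identifier	synonyms
Homo sapiens	9606	human|humans|h. sapiens
Mus musculus	10090	mouse|house mouse|m. musculus
Rattus norvegicus	10116	rat|norway rat
Arabidopsis thaliana	3702	thale cress
Saccharomyces cerevisiae	4932	baker's yeast|yeast
Escherichia coli	562	e. coli
Danio rerio	7955	zebrafish
Caenorhabditis elegans	6239	c. elegans
Drosophila melanogaster	7227	fruit fly
Zea mays	4577	maize|corn
Oryza sativa	4530	rice
Sus scrofa	9823	pig|swine
Bos taurus	9913	cattle|cow
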