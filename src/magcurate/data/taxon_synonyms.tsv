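label	mapped_taxa
Snowella	Cyanobacteria
Synechococcus	Cyanobacteria
Leptolyngbya	Cyanobacteria
Phormidium	Cyanobacteria
FamilyI	Cyanobacteria
Flavobacterium	Flavobacteriaceae;Bacteroidetes
Hydrogenophaga	Betaproteobacteria;Burkholderiales
Limnobacter	Betaproteobacteria;Burkholderiales
Brevundimonas	Alphaproteobacteria
Rhodobacteraceae	Rhodobacteraceae;Alphaproteobacteria
Arenimonas	Xanthomonadaceae;Gammaproteobacteria
Sphingomonadaceae	Sphingomonadaceae;Sphingomonadales;Alphaproteobacteria
Polymorphobacter	Sphingomonadaceae;Sphingomonadales;Alphaproteobacteria
Devosia	Rhizobiales;Alphaproteobacteria
Pseudomonas	Gammaproteobacteria
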