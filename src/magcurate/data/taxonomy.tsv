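label	lineage
Bacteria	Bacteria
Cyanobacteria	Bacteria;Cyanobacteria
Proteobacteria	Bacteria;Proteobacteria
Alphaproteobacteria	Bacteria;Proteobacteria;Alphaproteobacteria
Sphingomonadales	Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales
Sphingomonadaceae	Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae
Rhodobacteraceae	Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae
Rhizobiales	Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales
Betaproteobacteria	Bacteria;Proteobacteria;Betaproteobacteria
Burkholderiales	Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales
Gammaproteobacteria	Bacteria;Proteobacteria;Gammaproteobacteria
Xanthomonadaceae	Bacteria;Proteobacteria;Gammaproteobacteria;Xanthomonadales;Xanthomonadaceae
Bacteroidetes	Bacteria;Bacteroidetes
Flavobacteriaceae	Bacteria;Bacteroidetes;Flavobacteriales;Flavobacteriaceae
Cytophagales	Bacteria;Bacteroidetes;Cytophagales
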