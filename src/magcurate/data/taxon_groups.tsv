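group	label
proteobacteria	Alphaproteobacteria
proteobacteria	Betaproteobacteria
proteobacteria	Gammaproteobacteria
proteobacteria	Sphingomonadales
proteobacteria	Xanthomonadaceae
proteobacteria	Burkholderiales
proteobacteria	Rhizobiales
bacteroidetes	Bacteroidetes
bacteroidetes	Flavobacteriaceae
bacteroidetes	Cytophagales
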