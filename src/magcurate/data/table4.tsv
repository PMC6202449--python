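strain	taxon_label	top_hit	source_bin	affiliated_bin	coverage
ULC335	Snowella	Snowella litoralis 1LT47S05	bin0	bin1	37.00
ULC335	Brevundimonas	Uncultured Brevundimonas sp.	bin0		22.23
ULC335	Flavobacterium	Uncultured bacterium clone N4_091	bin0	bin2	58.44
ULC335	Unclassified	na	bin0		10.25
ULC335	Hydrogenophaga	Hydrogenophaga palleronii	bin0		9.64
ULC335	Rhodobacteraceae	Uncultured bacterium clone ZWB3-3	bin0		7.79
ULC007	Leptolyngbya	Phormidesmis priestleyi ANT.LG2.4 16S	bin0	bin1	85.23
ULC027	Unclassified	na	bin2	bin2*	54.08
ULC041	Leptolyngbya	Leptolyngbya antarctica ANT.LACV6.1	bin0	bin1	97.23
ULC065	Arenimonas	Uncultured bacterium clone a33	bin0	bin2	40.66
ULC065	Synechococcus	Cyanobium sp. JJ17-5	bin0	bin1	165.13
ULC066	Limnobacter	Uncultured bacterium clone S25	bin0	bin3	14.15
ULC066	Unclassified	na	bin0		21.51
ULC066	FamilyI	Pseudanabaena biceps PCC 7429	bin0	bin1	50.06
ULC068	FamilyI	Pseudanabaena sp. Sai012	bin0	bin1	68.53
ULC073	Sphingomonadaceae	Blastomonas sp. AAP25	bin6	bin6*	31.87
ULC073	Leptolyngbya	Leptolyngbya antarctica ANT.LACV6.1	bin0	bin1	33.60
ULC073	Limnobacter	Uncultured bacterium clone B3NR69D12	bin0	bin2	19.58
ULC077	Unclassified	na	bin0	bin1	52.80
ULC082	Hydrogenophaga	Uncultured Comamonadaceae bacterium	bin0		18.85
ULC082	Brevundimonas	Uncultured alphaproteobacterium clone KWK6S.50	bin0		25.08
ULC082	Unclassified	na	bin0		32.77
ULC082	Pseudomonas	Pseudomonas sp. WCS374	bin0		32.71
ULC082	Synechococcus	Synechococcus sp. MW97C4	bin0	bin1	93.93
ULC084	Brevundimonas	Uncultured alphaproteobacterium	bin0	bin2	31.39
ULC084	Synechococcus	Uncultured bacterium clone MS81	bin0	bin3	87.30
ULC084	Limnobacter	Uncultured bacterium clone B3NR69D12	bin0	bin1	16.99
ULC129	Phormidium	Uncultured bacterium clone GBII-52	bin0	bin1	52.71
ULC146	Sphingomonadaceae	Blastomonas sp. AAP25	bin3	bin3*	81.39
ULC146	Flavobacterium	Flavobacterium sp. Leaf359	bin0	bin2	25.91
ULC146	Hydrogenophaga	Hydrogenophaga sp. Root209	bin1	bin1*	61.13
ULC165	Unclassified	na	bin0		85.20
ULC165	Unclassified	na	bin0		98.62
ULC179	Devosia	Devosia psychrophila strain Cr7-05	bin0		97.88
ULC179	Unclassified	na	bin0		16.43
ULC179	Polymorphobacter	Uncultured Sphingomonadaceae bacterium	bin3	bin3*	91.23
ULC186	FamilyI	Leptolyngbya sp. 0BB32S02	bin0	bin1	116.04
ULC187	FamilyI	Pseudanabaena sp. Sai010	bin0	bin1	81.01
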