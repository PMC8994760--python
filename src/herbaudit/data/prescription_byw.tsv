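preparation	phm	phs	processed
BYW	Leonuri herba	Leonurus japonicus	false
BYW	Codonopsis radix	Codonopsis pilosula;Codonopsis tangshen	false
BYW	Atractylodis macrocephalae rhizoma	Atractylodes macrocephala	false
BYW	Glycyrrhizae radix	Glycyrrhiza uralensis;Glycyrrhiza inflata;Glycyrrhiza glabra	false
BYW	Angelicae sinensis radix	Angelica sinensis	false
BYW	Paeoniae radix alba	Paeonia lactiflora	false
BYW	Chuanxiong rhizoma	Ligusticum chuanxiong	false
BYW	Rehmanniae radix praeparata	Rehmannia glutinosa	true
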