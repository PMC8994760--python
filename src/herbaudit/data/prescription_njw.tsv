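preparation	phm	phs	processed
NJW	Paeoniae radix alba	Paeonia lactiflora	false
NJW	Codonopsis radix	Codonopsis pilosula	false
NJW	Astragali radix	Astragalus membranaceus;Astragalus mongholicus	false
NJW	Cassiae semen	Senna obtusifolia;Senna tora	false
NJW	Chuanxiong rhizoma	Ligusticum chuanxiong	false
NJW	Scutellariae radix extract	Scutellaria baicalensis	true
NJW	Nardostachyos radix et rhizoma	Nardostachys jatamansi;Nardostachys chinensis	false
NJW	Menthae haplocalycis herba	Mentha haplocalyx	false
NJW	Curcumae radix	Curcuma wenyujin;Curcuma longa;Curcuma kwangsiensis;Curcuma phaeocaulis	false
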