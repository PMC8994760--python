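species	DHW.A.I1	DHW.A.I2	DHW.A.I3	DHW.A.II1	DHW.A.II2	DHW.A.II3	DHW.A.III1	DHW.A.III2	DHW.A.III3	DHW.B.I1	DHW.B.I2	DHW.B.I3	DHW.B.II1	DHW.B.II2	DHW.B.II3	DHW.B.III1	DHW.B.III2	DHW.B.III3
Aconitum kusnezoffii	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
Amomum compactum	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Anemone raddeana	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Angelica sinensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Aquilaria sinensis	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0
Asarum heterotropoides	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0
Asarum sieboldii	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Atractylodes macrocephala	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0
Clematis hexapetala	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Commiphora myrrha	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Coptis chinensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Coptis deltoidea	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
Coptis teeta	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Cyperus rotundus	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
Ephedra equisetina	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Ephedra intermedia	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0
Ephedra sinica	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Gastrodia elata	0	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0	0	0
Glycyrrhiza glabra	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0
Glycyrrhiza uralensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Lindera aggregata	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Notopterygium franchetii	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Notopterygium incisum	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Osmunda japonica	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0
Paeonia lactiflora	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Paeonia veitchii	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Panax ginseng	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Pogostemon cablin	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0
Rheum officinale	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0
Rheum palmatum	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0
Rheum tanguticum	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	0	0
Saposhnikovia divaricata	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0
Scrophularia ningpoensis	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0
Scutellaria baicalensis	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0
Styrax tonkinensis	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0
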