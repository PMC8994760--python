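species	DHW.A.I1	DHW.A.I2	DHW.A.I3	DHW.A.II1	DHW.A.II2	DHW.A.II3	DHW.A.III1	DHW.A.III2	DHW.A.III3	DHW.B.I1	DHW.B.I2	DHW.B.I3	DHW.B.II1	DHW.B.II2	DHW.B.II3	DHW.B.III1	DHW.B.III2	DHW.B.III3
Anemone raddeana	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Angelica sinensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Aquilaria sinensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0
Asarum heterotropoides	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0
Asarum sieboldii	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0
Atractylodes macrocephala	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Boswellia neglecta	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Cinnamomum cassia	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Clematis hexapetala	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0
Coptis chinensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Coptis deltoidea	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Cyperus rotundus	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0
Ephedra equisetina	0	0	0	0	0	1	0	0	1	0	0	0	0	0	0	0	0	0
Ephedra sinica	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0
Glycyrrhiza uralensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Panax ginseng	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Pogostemon cablin	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Rehmannia glutinosa	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Rheum officinale	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0
Rheum tanguticum	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0
Scrophularia ningpoensis	0	1	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0
Scutellaria baicalensis	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
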