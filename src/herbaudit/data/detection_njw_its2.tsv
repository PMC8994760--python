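species	NJW.A.I1	NJW.A.I2	NJW.A.I3	NJW.A.II1	NJW.A.II2	NJW.A.II3	NJW.A.III1	NJW.A.III2	NJW.A.III3	NJW.B.I1	NJW.B.I2	NJW.B.I3	NJW.B.II1	NJW.B.II2	NJW.B.II3	NJW.B.III1	NJW.B.III2	NJW.B.III3
Astragalus membranaceus	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Codonopsis pilosula	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0
Curcuma kwangsiensis	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Curcuma longa	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Curcuma wenyujin	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
Ligusticum chuanxiong	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Mentha haplocalyx	1	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0
Nardostachys jatamansi	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0
Paeonia lactiflora	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Scutellaria baicalensis	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0
Senna obtusifolia	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
Senna tora	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
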