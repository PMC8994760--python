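preparation	phm	phs	processed
YGW	Aconitum carmichaelii Debx	Aconitum carmichaeli	true
YGW	Angelica sinensis (Oliv.) Diels	Angelica sinensis	false
YGW	Cinnamomum cassia Presl	Cinnamomum cassia	false
YGW	Cornus officinalis Sieb. et Zucc	Cornus officinalis	false
YGW	Cuscuta australis R. Br	Cuscuta australis;Cuscuta chinensis	false
YGW	Dioscorea opposita Thunb	Dioscorea opposita	true
YGW	Eucommia ulmoides Oliv	Eucommia ulmoides	false
YGW	Lycium barbarum L.	Lycium barbarum	false
YGW	Rehmanniae radix praeparata	Rehmannia glutinosa	true
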