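preparation	phm	phs	processed
DHW	Clematidis radix	Clematis chinensis;Clematis hexapetala;Clematis manshurica	false
DHW	Anemones raddeanae rhizoma	Anemone raddeana	true
DHW	Aconiti kusnezoffii radix cocta	Aconitum kusnezoffii	true
DHW	Gastrodiae rhizoma	Gastrodia elata	false
DHW	Polygoni multiflori radix	Polygonum multiflorum	false
DHW	Ephedrae herba	Ephedra sinica;Ephedra intermedia;Ephedra equisetina	false
DHW	Osmundae rhizoma	Osmunda japonica	false
DHW	Glycyrrhizae radix	Glycyrrhiza uralensis;Glycyrrhiza inflata;Glycyrrhiza glabra	false
DHW	Notopterygii rhizoma et radix	Notopterygium incisum;Notopterygium franchetii	false
DHW	Cinnamomi cortex	Cinnamomum cassia	false
DHW	Pogostemonis herba	Pogostemon cablin	false
DHW	Linderae radix	Lindera aggregata	false
DHW	Coptidis rhizoma	Coptis chinensis;Coptis deltoidea;Coptis teeta	false
DHW	Rhei radix et rhizoma praeparata	Rheum palmatum;Rheum tanguticum;Rheum officinale	true
DHW	Aucklandiae radix	Aucklandia lappa	false
DHW	Aquilariae lignum resinatum	Aquilaria sinensis	false
DHW	Asari radix et rhizoma	Asarum heterotropoides;Asarum sieboldii	false
DHW	Paeoniae radix rubra	Paeonia lactiflora;Paeonia veitchii	false
DHW	Myrrha	Commiphora myrrha;Commiphora molmol	false
DHW	Caryophylli flos	Eugenia caryophyllata	false
DHW	Olibanum	Boswellia carterii;Boswellia bhaw-dajiana;Boswellia neglecta	false
DHW	Arisaematis rhizoma praeparatum	Arisaema erubescens;Arisaema heterophyllum;Arisaema amurense	true
DHW	Citri reticulatae pericarpium viride	Citrus reticulata	false
DHW	Drynariae rhizoma	Drynaria fortunei	false
DHW	Amomi fructus rotundus	Amomum kravanh;Amomum compactum	false
DHW	Benzoinum	Styrax tonkinensis	false
DHW	Cyperi rhizoma	Cyperus rotundus	true
DHW	Scrophulariae radix	Scrophularia ningpoensis	false
DHW	Atractylodis macrocephalae rhizoma	Atractylodes macrocephala	true
DHW	Saposhnikoviae radix	Saposhnikovia divaricata	false
DHW	Puerariae lobatae radix	Pueraria lobata	false
DHW	Angelicae sinensis radix	Angelica sinensis	false
DHW	Draconis sanguis	Daemonorops draco	false
DHW	Ginseng radix et rhizoma	Panax ginseng	false
DHW	Rehmanniae radix praeparata	Rehmannia glutinosa	true
DHW	Scutellariae radix	Scutellaria baicalensis	false
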