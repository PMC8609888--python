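taxon	Calpha	Cbeta	Cgamma
Cnidaria	1	0	0
Xenacoelomorpha	0	0	0
Rotifera	1	0	0
Micrognathozoa	0	0	0
Cycliophora	0	0	0
Platyhelminthes	0	0	0
Gastrotricha	0	0	0
Bryozoa	1	1	1
Annelida	1	1	1
Mollusca	1	1	1
Nemertea	1	1	0
Brachiopoda	1	1	1
Phoronida	1	1	1
Priapulida	1	0	0
Loricifera	1	0	0
Tardigrada	1	0	0
Nematoda	1	0	0
Onychophora	0	1	0
Arthropoda	1	1	0
Echinodermata	0	1	0
Tunicata	0	1	0
Craniata	0	1	0
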