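(Cnidaria,(Xenacoelomorpha,((((Rotifera,(Micrognathozoa,Cycliophora))Gnathifera,((Platyhelminthes,Gastrotricha)Rouphozoa,(Bryozoa,(Annelida,(Mollusca,(Nemertea,(Brachiopoda,Phoronida)Brachiozoa))))Trochozoa)Platytrochozoa)Spiralia,((Priapulida,Loricifera)Scalidophora,(Nematoda,(Tardigrada,(Onychophora,Arthropoda))Panarthropoda))Ecdysozoa)Protostomia,(Echinodermata,(Tunicata,Craniata)Olfactores)Deuterostomia)Nephrozoa)Bilateria)Planulozoa;
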