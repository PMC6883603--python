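# Trade name -> generic name alias table used to flag trade-name drug entries.
Gleevec	Imatinib
Iressa	Gefitinib
Tarceva	Erlotinib
Tagrisso	Osimertinib
Herceptin	Trastuzumab
Zelboraf	Vemurafenib
Tafinlar	Dabrafenib
Mekinist	Trametinib
Erbitux	Cetuximab
Avastin	Bevacizumab
Keytruda	Pembrolizumab
Xalkori	Crizotinib
Sprycel	Dasatinib
Taxol	Paclitaxel
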