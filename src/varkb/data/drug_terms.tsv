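# Miniature NCI Thesaurus drug table (flat; no parentage). Synthetic curated
# fixture for offline use; generic names keyed by NCIt-style codes.
NCIT:C62035	Imatinib		drug
NCIT:C1855	Gefitinib		drug
NCIT:C65530	Erlotinib		drug
NCIT:C116377	Osimertinib		drug
NCIT:C1647	Trastuzumab		drug
NCIT:C64768	Vemurafenib		drug
NCIT:C82386	Dabrafenib		drug
NCIT:C77908	Trametinib		drug
NCIT:C1723	Cetuximab		drug
NCIT:C2039	Bevacizumab		drug
NCIT:C106432	Pembrolizumab		drug
NCIT:C68814	Crizotinib		drug
NCIT:C66876	Dasatinib		drug
NCIT:C1872	Paclitaxel		drug
NCIT:C1444	Carboplatin		drug
NCIT:C405	Cisplatin		drug
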