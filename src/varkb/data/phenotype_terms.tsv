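# Miniature Human Phenotype Ontology subset. Synthetic curated fixture for
# offline use; ids are well-known HP accessions, parentage simplified.
HP:0000001	All		phenotype
HP:0000118	Phenotypic abnormality	HP:0000001	phenotype
HP:0002664	Neoplasm	HP:0000118	phenotype
HP:0100526	Neoplasm of the lung	HP:0002664	phenotype
HP:0003002	Breast carcinoma	HP:0002664	phenotype
HP:0001909	Leukemia	HP:0002664	phenotype
HP:0012125	Prostate cancer	HP:0002664	phenotype
HP:0002896	Neoplasm of the liver	HP:0002664	phenotype
HP:0100615	Ovarian neoplasm	HP:0002664	phenotype
HP:0002861	Melanoma	HP:0002664	phenotype
HP:0030692	Brain neoplasm	HP:0002664	phenotype
HP:0001250	Seizure	HP:0000118	phenotype
HP:0004322	Short stature	HP:0000118	phenotype
HP:0000252	Microcephaly	HP:0000118	phenotype
HP:0001945	Fever	HP:0000118	phenotype
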