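# Miniature Disease Ontology cancer branch. Synthetic curated fixture for
# offline use; ids are well-known DOID accessions, parentage simplified.
DOID:162	cancer		disease
DOID:2531	hematologic cancer	DOID:162	disease
DOID:1240	leukemia	DOID:2531	disease
DOID:9119	acute myeloid leukemia	DOID:1240	disease
DOID:8552	chronic myeloid leukemia	DOID:1240	disease
DOID:0060058	lymphoma	DOID:2531	disease
DOID:1324	lung cancer	DOID:162	disease
DOID:3908	lung non-small cell carcinoma	DOID:1324	disease
DOID:3910	lung adenocarcinoma	DOID:3908	disease
DOID:5409	lung small cell carcinoma	DOID:1324	disease
DOID:1612	breast cancer	DOID:162	disease
DOID:9256	colorectal cancer	DOID:162	disease
DOID:1909	melanoma	DOID:162	disease
DOID:3068	glioblastoma	DOID:162	disease
DOID:1793	pancreatic cancer	DOID:162	disease
DOID:10283	prostate cancer	DOID:162	disease
DOID:684	hepatocellular carcinoma	DOID:162	disease
DOID:2394	ovarian cancer	DOID:162	disease
DOID:10534	stomach cancer	DOID:162	disease
DOID:4450	renal cell carcinoma	DOID:162	disease
DOID:1781	thyroid cancer	DOID:162	disease
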