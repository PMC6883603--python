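# Miniature Sequence Ontology subtree rooted at sequence_variant.
# Synthetic curated fixture for offline use; ids are well-known SO accessions,
# parentage simplified to is_a paths relevant to variant-type curation.
SO:0001060	sequence_variant		sequence
SO:0001537	structural_variant	SO:0001060	sequence
SO:0001565	gene_fusion	SO:0001537	sequence
SO:0001886	transcript_fusion	SO:0001537	sequence
SO:0000199	translocation	SO:0001537	sequence
SO:0001019	copy_number_variation	SO:0001537	sequence
SO:0001742	copy_number_gain	SO:0001019	sequence
SO:0001743	copy_number_loss	SO:0001019	sequence
SO:0000159	deletion	SO:0001537	sequence
SO:0000667	insertion	SO:0001537	sequence
SO:1000036	inversion	SO:0001537	sequence
SO:1000035	duplication	SO:0001537	sequence
SO:0001483	SNV	SO:0001060	sequence
SO:0001576	transcript_variant	SO:0001060	sequence
SO:0001580	coding_sequence_variant	SO:0001576	sequence
SO:0001818	protein_altering_variant	SO:0001580	sequence
SO:0001583	missense_variant	SO:0001818	sequence
SO:0001587	stop_gained	SO:0001818	sequence
SO:0001578	stop_lost	SO:0001818	sequence
SO:0002012	start_lost	SO:0001818	sequence
SO:0001589	frameshift_variant	SO:0001818	sequence
SO:0001821	inframe_insertion	SO:0001818	sequence
SO:0001822	inframe_deletion	SO:0001818	sequence
SO:0001819	synonymous_variant	SO:0001580	sequence
SO:0001627	intron_variant	SO:0001576	sequence
SO:0001623	5_prime_UTR_variant	SO:0001576	sequence
SO:0001624	3_prime_UTR_variant	SO:0001576	sequence
SO:0001630	splice_region_variant	SO:0001576	sequence
SO:0001575	splice_donor_variant	SO:0001630|SO:0001627	sequence
SO:0001574	splice_acceptor_variant	SO:0001630|SO:0001627	sequence
SO:0001893	transcript_ablation	SO:0001576	sequence
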