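# Synthetic KRAS exon 2 codon-12 assay (G12V, GGT->GTT point
# substitution in a short synthetic context sequence). A point
# substitution yields few mutation-informative dispensations, so this
# assay needs a tighter noise scale than the deletion assay to reach
# its 5-10% limit of detection.
name: kras_ex2_g12v
wt_template: TGGAGCTGGTGGCGTAGGCAAGA
mut_template: TGGAGCTGTTGGCGTAGGCAAGA
dispensation_order: ACGT
noise_sd: 0.03
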