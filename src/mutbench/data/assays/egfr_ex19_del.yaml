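# Synthetic EGFR exon 19 deletion assay (15-bp in-frame deletion,
# E746_A750del-style). Templates are short synthetic read-direction
# sequences around the deletion hotspot, not a proprietary assay design.
name: egfr_ex19_del
wt_template: ATCAAGGAATTAAGAGAAGCAACATCTCCGAAAGCCAAC
mut_template: ATCAAGAACATCTCCGAAAGCCAAC
dispensation_order: ACGT
noise_sd: 0.05
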