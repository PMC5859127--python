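gene_type	category
protein_coding	protein-coding
lincRNA	lncRNA
lncRNA	lncRNA
antisense	lncRNA
processed_transcript	lncRNA
sense_intronic	lncRNA
sense_overlapping	lncRNA
3prime_overlapping_ncRNA	lncRNA
3prime_overlapping_ncrna	lncRNA
bidirectional_promoter_lncRNA	lncRNA
macro_lncRNA	lncRNA
non_coding	lncRNA
known_ncrna	lncRNA
miRNA	small RNA
snoRNA	small RNA
snRNA	small RNA
misc_RNA	small RNA
scaRNA	small RNA
rRNA	small RNA
Mt_rRNA	small RNA
Mt_tRNA	small RNA
sRNA	small RNA
scRNA	small RNA
vaultRNA	small RNA
vault_RNA	small RNA
ribozyme	small RNA
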