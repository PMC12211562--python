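# Default target fixture: 2,000 bp amplicon, 90 bp Avitag-Myc insert at
# position 1,000, 50 bp homology arms, three barcoded samples, and a
# silent PAM-edit readout site in the left homology arm.
gene: demo_locus
amplicon:
  fasta: default_amplicon.fasta
  record: amplicon
left_arm: ACGGTCATCACGTGATAGATCCCACGCTGTGCGATCAAGTAACAGTGTAA
right_arm: GAGGGAAAATGGGCGACCCCTGACAGCTTATCTAATCATGTCTTATGTTG
tag: GGTCTGAACGACATCTTCGAAGCTCAGAAAATCGAATGGCACGAAGGAGGTAGTGGAGGTGAACAAAAACTCATCTCAGAAGAGGATCTG
insertion_point: 1000
fwd_universal: GCAGTCGAACATGTAGCTGACTCAGGTCAC
rev_universal: TGGATCACTTGTGCAAGCATCACATCGTAG
umi_length: 8
barcodes:
  - {sample: emb1, fwd: ACGTAACT, rev: TGCATGGA}
  - {sample: emb2, fwd: CATGCTTC, rev: GTACGCAG}
  - {sample: emb3, fwd: AGTCAGTC, rev: TCAGTCAA}
snp_site: {position: 994, ref: G, template: A}
prefix_check_len: 30
prefix_max_edits: 6
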