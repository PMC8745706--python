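# AR-Amp-2: two independent AR amplicons (exon 1 and exon 2, both FAM) against
# two references, X-chromosomal MYM (ZMYM3) and chromosome-6 TBP (both HEX).
assay_id: AR-Amp-2
targets:
  - name: AR-X1
    channel: CH1_FAM
    amplitude_level: 4000.0
    role: gene_target
    chromosome: X
    alleles_per_normal_cell: {male: 1, female: 2}
  - name: AR-X2
    channel: CH1_FAM
    amplitude_level: 9000.0
    role: gene_target
    chromosome: X
    alleles_per_normal_cell: {male: 1, female: 2}
  - name: MYM
    channel: CH2_HEX
    amplitude_level: 3500.0
    role: reference
    chromosome: X
    alleles_per_normal_cell: {male: 1, female: 2}
  - name: TBP
    channel: CH2_HEX
    amplitude_level: 8000.0
    role: reference
    chromosome: "6"
    alleles_per_normal_cell: {male: 2, female: 2}
probe_metadata:
  AR-X1:
    amplicon: AR exon 1
    forward_primer: "CCTATGCAAATGCCTGCCTG"
    reverse_primer: "GCACTCTGCATTCGTTTCCC"
    primer_nM: 500
    probe: "[6FAM]AAGTCCGGTACAAAGCCAG[BHQ1]"
    probe_nM: 125
  AR-X2:
    amplicon: AR exon 2
    forward_primer: "TTTCCACCCCAGAAGACCTG"
    reverse_primer: "AAGACCTTGCAGCTTCCACA"
    primer_nM: 500
    probe: "[6FAM]CACCCAGAAGCTTCATCTC[BHQ1]"
    probe_nM: 250
  MYM:
    gene: zinc finger MYM-type protein 3
    forward_primer: "ACAGGGAACAGAACAAGCTGGTCTT"
    reverse_primer: "GCAAGACCCTGTGTAAGAACTTTGA"
    primer_nM: 1000
    probe: "[HEX]CATTACGATCCACATGTGATAG[BHQ]"
    probe_nM: 250
  TBP:
    gene: TATA-binding protein
    forward_primer: "ACAGAAGTTGGGTTTTCCAGC"
    reverse_primer: "TCACATCACAGCTCCCCAC"
    primer_nM: 500
    probe: "[HEX]TCTTGGACTTCAAGATTCAG[BHQ1]"
    probe_nM: 500
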