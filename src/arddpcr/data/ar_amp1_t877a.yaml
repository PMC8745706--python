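# AR-Amp-1/T877A: AR exon 8 mutant/wild-type duplex with RPP30 reference.
# Amplitude levels are simulator defaults (arbitrary fluorescence units),
# chosen so same-channel bands and their pairwise sums are well separated.
assay_id: AR-Amp-1/T877A
targets:
  - name: MT
    channel: CH1_FAM
    amplitude_level: 5000.0
    role: mutant
    chromosome: X
    alleles_per_normal_cell: {male: 1, female: 2}
  - name: WT
    channel: CH2_HEX
    amplitude_level: 3000.0
    role: wildtype
    chromosome: X
    alleles_per_normal_cell: {male: 1, female: 2}
  - name: RPP30
    channel: CH2_HEX
    amplitude_level: 7000.0
    role: reference
    chromosome: "10"
    alleles_per_normal_cell: {male: 2, female: 2}
probe_metadata:
  AR-X8:
    amplicon: AR exon 8 (T877A codon)
    forward_primer: "CCCTACAGATTGCGAGAGAGC"
    reverse_primer: "GAAAGTCCACGCTCACCATGT"
    primer_nM: 500
  MT:
    probe: "[6FAM]ATCAGTTCGCTTTTGACCTG[BHQ1]"
    probe_nM: 250
  WT:
    probe: "[HEX]ATCAGTTCACTTTTGACCTG[BHQ1]"
    probe_nM: 250
  RPP30:
    gene: ribonuclease P/MRP subunit p30
    forward_primer: "GATTTGGACCTGCGAGCG"
    reverse_primer: "GCGGCTGTCTCCACAAGT"
    primer_nM: 500
    probe: "[HEX]TCTGACCTGAAGGCTCTG[BHQ1]"
    probe_nM: 250
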