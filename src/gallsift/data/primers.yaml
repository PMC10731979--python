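# Published marker primers and probe for the specific gall fragment (SGF)
# and the TaqMan qPCR assay.  Expected SGF PCR product: 471 bp.
SGF-F:
  seq: CTTGACATGTTCTGGAGCGG
SGF-R:
  seq: AACGAGCGTGGTACTGTGAT
AI7ZYBP-F:
  seq: TGTTCGCTGCACAGAGTTCT
AI7ZYBP-R:
  seq: GGCTTGAGTGCTTCGATTTCG
AI7ZYBP-probe:
  seq: TCTGCCACCGGACCCT
  probe: true
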