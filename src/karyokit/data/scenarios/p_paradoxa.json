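{
  "name": "P_PARADOXA",
  "apply_to_homologues": true,
  "events": [
    {
      "kind": "RDNA_LOSS",
      "label": "B3",
      "family": "5S",
      "note": "loss of the B3 5S repeats from the ancestral B karyotype"
    },
    {
      "kind": "PERICENTRIC_INVERSION",
      "chrom_label": "B2",
      "frac_short": 0.45,
      "frac_long": 0.40,
      "note": "pericentric inversion of the 5S-bearing B2; breakpoints illustrative"
    }
  ]
}
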