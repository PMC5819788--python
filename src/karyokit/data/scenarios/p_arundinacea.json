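{
  "name": "P_ARUNDINACEA",
  "apply_to_homologues": true,
  "events": [
    {
      "kind": "AUTOPOLYPLOIDY",
      "factor": 2,
      "note": "whole-genome duplication of a B-genome diploid"
    },
    {
      "kind": "PERICENTRIC_INVERSION",
      "chrom_label": "B1",
      "frac_short": 0.50,
      "frac_long": 0.25,
      "note": "pericentric inversion in B1; breakpoints illustrative"
    },
    {
      "kind": "RDNA_LOSS",
      "label": "B2",
      "family": "5S",
      "limit": 2,
      "note": "loss of one 5S pair in B2 after duplication (dosage reduction)"
    }
  ]
}
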