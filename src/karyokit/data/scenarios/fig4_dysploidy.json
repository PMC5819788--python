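{
  "name": "FIG4_DYSPLOIDY",
  "apply_to_homologues": true,
  "events": [
    {
      "kind": "FISSION_PERICENTROMERIC",
      "chrom_label": "A7",
      "note": "pericentromeric break of the proximal-5S metacentric; centromere lost, both arms become acentric segments"
    },
    {
      "kind": "END_TO_END_FUSION",
      "recipient_label": "A2",
      "recipient_arm": "SHORT",
      "segment_origin": "A7",
      "segment_arm": "LONG",
      "note": "5S-bearing half translocated telomere-to-telomere onto proto-A2"
    },
    {
      "kind": "END_TO_END_FUSION",
      "recipient_label": "A6",
      "recipient_arm": "SHORT",
      "segment_origin": "A7",
      "segment_arm": "SHORT",
      "note": "other half fused onto proto-A6"
    },
    {
      "kind": "PERICENTRIC_INVERSION",
      "chrom_label": "A2",
      "frac_short": 1.0,
      "frac_long": 0.2,
      "note": "pericentric inversion spanning the whole short arm; shifts the centromere, yielding a subtelocentric A2 with both 5S on the long arm"
    },
    {
      "kind": "PERICENTRIC_INVERSION",
      "chrom_label": "A6",
      "frac_short": 1.0,
      "frac_long": 0.5,
      "note": "pericentric inversion of the fused A6; submetacentric outcome"
    }
  ]
}
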