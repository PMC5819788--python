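{
  "name": "P_MINOR",
  "apply_to_homologues": true,
  "events": [
    {
      "kind": "ALLOPOLYPLOID_MERGE",
      "partner": "GENOME_C_TEMPLATE",
      "species": "B/C allotetraploid (minor-like)",
      "note": "amphidiploid union of a B-genome and a C-genome diploid"
    },
    {
      "kind": "RDNA_LOSS",
      "genome": "C",
      "family": "45S",
      "note": "nucleolar dominance: the 45S loci inherited from the C parent are silenced and lost"
    }
  ]
}
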