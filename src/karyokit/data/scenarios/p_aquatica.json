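{
  "name": "P_AQUATICA",
  "apply_to_homologues": true,
  "events": [
    {
      "kind": "ALLOPOLYPLOID_MERGE",
      "partner": "GENOME_C_TEMPLATE",
      "species": "B/C allotetraploid (aquatica-like)",
      "note": "amphidiploid union of a B-genome and a C-genome diploid"
    }
  ]
}
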