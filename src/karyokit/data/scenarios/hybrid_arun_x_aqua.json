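{
  "name": "HYBRID_ARUN_X_AQUA",
  "apply_to_homologues": true,
  "events": [
    {
      "kind": "ALLOPOLYPLOID_MERGE",
      "partner": "P. aquatica",
      "species": "P. arundinacea x P. aquatica",
      "note": "octoploid hybrid of the two tetraploids, 2n = 8x = 56"
    }
  ]
}
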