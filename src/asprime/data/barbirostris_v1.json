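{
  "schema_version": 1,
  "name": "barbirostris_v1",
  "forward_primers": [
    {
      "name": "BARA4_F",
      "core": "AATAGTAGGAACTTCTTTATGA",
      "tail": "GCGGGCAGGGCGGCGGGGGCGGGGCC",
      "orientation": "forward",
      "target_species": "An. barbirostris s.s.",
      "engineered_mismatch": null
    },
    {
      "name": "BARA1_F",
      "core": "ATTACTACTGTTATTAATATAGGA",
      "tail": "",
      "orientation": "forward",
      "target_species": "An. dissidens",
      "engineered_mismatch": null
    },
    {
      "name": "BARA2_F",
      "core": "TTAGGTCACCCAGGAGCA",
      "tail": "",
      "orientation": "forward",
      "target_species": "An. saeungae",
      "engineered_mismatch": null
    },
    {
      "name": "BARWEJ_F",
      "core": "GATTTGGAAACTGATTACTG",
      "tail": "",
      "orientation": "forward",
      "target_species": "An. wejchoochotei",
      "engineered_mismatch": null
    },
    {
      "name": "BARA3_F",
      "core": "CGGAACTGGATGAACTGTA",
      "tail": "",
      "orientation": "forward",
      "target_species": "An. barbirostris A3",
      "engineered_mismatch": null
    }
  ],
  "reverse_primer": {
    "name": "HCO_2198_R",
    "core": "TAAACTTCAGGGTGACCAAAAAATCA",
    "tail": "",
    "orientation": "reverse",
    "target_species": "universal",
    "engineered_mismatch": null
  },
  "expected_sizes": {
    "An. barbirostris s.s.": 706,
    "An. dissidens": 238,
    "An. saeungae": 611,
    "An. wejchoochotei": 502,
    "An. barbirostris A3": 365
  },
  "size_tolerance": 10,
  "min_gap": 60,
  "notes": "Validated allele-specific multiplex for the Anopheles Barbirostris Complex: five species-specific forward primers plus the universal Folmer reverse primer HCO-2198. The published assay carries deliberate offset-3 mismatches in the BARA4_F, BARA1_F and BARWEJ_F cores; those substituted bases are already part of the core sequences as synthesized, so no engineered_mismatch annotation (original base vs substituted base) is recorded here. The 26-nt GC tail on BARA4_F lengthens the An. barbirostris s.s. product from 680 to 706 bp to separate it from the 611 bp An. saeungae band."
}
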