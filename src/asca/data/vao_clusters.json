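{
  "reference_id": "PsVAO",
  "clusters": [
    {
      "name": "A",
      "positions": [316, 413, 469, 470],
      "role": "coordination of the para-substituent of phenolic substrates"
    },
    {
      "name": "H",
      "positions": [61, 422, 423],
      "role": "covalent binding of the FAD cofactor"
    },
    {
      "name": "P",
      "positions": [108, 424, 468, 503, 504],
      "role": "coordination of the phenolic moiety of the substrate"
    },
    {
      "name": "T",
      "positions": [184, 185, 459],
      "role": "gate between the substrate tunnel and the active site"
    },
    {
      "name": "W",
      "positions": [170, 188, 312, 409, 410, 457],
      "role": "catalysis; binding and activation of water molecules"
    }
  ],
  "expected_reference_residues": {
    "316": "L", "413": "W", "469": "V", "470": "C",
    "61": "H", "422": "H", "423": "L",
    "108": "Y", "424": "F", "468": "I", "503": "Y", "504": "R",
    "184": "G", "185": "V", "459": "T",
    "170": "D", "188": "T", "312": "R", "409": "D", "410": "E", "457": "T"
  }
}
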