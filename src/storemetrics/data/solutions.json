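{
  "solutions": [
    {
      "name": "CPD",
      "kind": "anticoagulant",
      "components": {
        "trisodium citrate": 89.0,
        "citric acid": 16.0,
        "monosodium phosphate": 16.0,
        "dextrose": 129.0
      },
      "pH": 5.6,
      "declared_osmolarity_mosm_l": 533
    },
    {
      "name": "CPD-N",
      "kind": "anticoagulant",
      "components": {
        "trisodium citrate": 89.0,
        "citric acid": 16.0,
        "monosodium phosphate": 16.0,
        "dextrose": 5.5
      },
      "pH": 5.6,
      "declared_osmolarity_mosm_l": 410
    },
    {
      "name": "AS-1",
      "kind": "additive",
      "components": {
        "dextrose": 111.0,
        "sodium chloride": 154.0,
        "adenine": 2.0,
        "mannitol": 41.0
      },
      "pH": 5.8,
      "declared_osmolarity_mosm_l": 465
    },
    {
      "name": "AS-1N",
      "kind": "additive",
      "components": {
        "dextrose": 5.5,
        "sodium chloride": 154.0,
        "adenine": 2.0,
        "mannitol": 41.0
      },
      "pH": 5.8,
      "declared_osmolarity_mosm_l": 357
    }
  ],
  "dissociation": {
    "trisodium citrate": 4,
    "citric acid": 1,
    "monosodium phosphate": 2,
    "dextrose": 1,
    "sodium chloride": 2,
    "adenine": 1,
    "mannitol": 1
  }
}
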