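{
  "instrument_id": "cfv",
  "schema_version": 1,
  "items": [
    "phy1",
    "phy2",
    "phy3",
    "phy4",
    "phy5",
    "phy6",
    "phy7",
    "phy8",
    "phy9",
    "ver1",
    "ver2",
    "ver3",
    "ver4",
    "wit1",
    "wit2",
    "wit3",
    "sex1",
    "sex2",
    "neg1",
    "neg2"
  ],
  "response_min": 0,
  "response_max": 1,
  "reverse_coded": [],
  "subscales": {
    "physical": [
      "phy1",
      "phy2",
      "phy3",
      "phy4",
      "phy5",
      "phy6",
      "phy7",
      "phy8",
      "phy9"
    ],
    "verbal_emotional": [
      "ver1",
      "ver2",
      "ver3",
      "ver4"
    ],
    "witnessed": [
      "wit1",
      "wit2",
      "wit3"
    ],
    "sexual": [
      "sex1",
      "sex2"
    ],
    "neglect": [
      "neg1",
      "neg2"
    ]
  }
}
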