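{
  "instrument_id": "pds_symptoms",
  "schema_version": 1,
  "items": [
    "s1",
    "s2",
    "s3",
    "s4",
    "s5",
    "s6",
    "s7",
    "s8",
    "s9",
    "s10",
    "s11",
    "s12",
    "s13",
    "s14",
    "s15",
    "s16",
    "s17"
  ],
  "response_min": 0,
  "response_max": 3,
  "reverse_coded": [],
  "subscales": {
    "severity": [
      "s1",
      "s2",
      "s3",
      "s4",
      "s5",
      "s6",
      "s7",
      "s8",
      "s9",
      "s10",
      "s11",
      "s12",
      "s13",
      "s14",
      "s15",
      "s16",
      "s17"
    ]
  }
}
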