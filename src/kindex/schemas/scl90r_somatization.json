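{
  "instrument_id": "scl90r_somatization",
  "schema_version": 1,
  "items": [
    "q1",
    "q2",
    "q3",
    "q4",
    "q5",
    "q6",
    "q7",
    "q8",
    "q9",
    "q10",
    "q11",
    "q12"
  ],
  "response_min": 0,
  "response_max": 4,
  "reverse_coded": [],
  "subscales": {
    "somatization": [
      "q1",
      "q2",
      "q3",
      "q4",
      "q5",
      "q6",
      "q7",
      "q8",
      "q9",
      "q10",
      "q11",
      "q12"
    ]
  }
}
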