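{
  "instrument_id": "pss4",
  "schema_version": 1,
  "items": [
    "q1",
    "q2",
    "q3",
    "q4"
  ],
  "response_min": 0,
  "response_max": 4,
  "reverse_coded": [
    "q2",
    "q3"
  ],
  "subscales": {
    "total": [
      "q1",
      "q2",
      "q3",
      "q4"
    ]
  }
}
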