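{
  "instrument_id": "pds_events",
  "schema_version": 1,
  "items": [
    "e1",
    "e2",
    "e3",
    "e4",
    "e5",
    "e6",
    "e7",
    "e8",
    "e9",
    "e10",
    "e11",
    "e12"
  ],
  "response_min": 0,
  "response_max": 1,
  "reverse_coded": [],
  "subscales": {
    "events": [
      "e1",
      "e2",
      "e3",
      "e4",
      "e5",
      "e6",
      "e7",
      "e8",
      "e9",
      "e10",
      "e11",
      "e12"
    ]
  }
}
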