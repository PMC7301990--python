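{
  "termset-5": {
    "id": "termset-5",
    "labels": ["fail", "pass", "good", "very good", "excellent"]
  },
  "termset-7": {
    "id": "termset-7",
    "labels": [
      "very poor",
      "poor",
      "slightly poor",
      "fair",
      "slightly good",
      "good",
      "very good"
    ]
  }
}
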