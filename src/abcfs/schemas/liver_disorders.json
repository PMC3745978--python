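{
  "name": "liver_disorders",
  "notes": "BUPA liver disorders dialect: 6 blood-test/drinks features, selector label last.",
  "has_header": false,
  "label": {"column": "selector", "position": 6, "values": ["1", "2"], "positive": "2"},
  "columns": [
    {"name": "mcv", "kind": "continuous", "range": [65, 103]},
    {"name": "alkphos", "kind": "continuous", "range": [23, 138]},
    {"name": "sgpt", "kind": "continuous", "range": [4, 155]},
    {"name": "sgot", "kind": "continuous", "range": [5, 82]},
    {"name": "gammagt", "kind": "continuous", "range": [5, 297]},
    {"name": "drinks", "kind": "continuous", "range": [0, 20]}
  ]
}
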