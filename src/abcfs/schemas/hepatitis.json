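{
  "name": "hepatitis",
  "notes": "UCI hepatitis dialect: label first, '?' missing marker; class 1=die, 2=live; binary attributes coded 1/2.",
  "has_header": false,
  "label": {"column": "class", "position": 0, "values": ["1", "2"], "positive": "1"},
  "columns": [
    {"name": "age", "kind": "continuous", "range": [7, 78]},
    {"name": "sex", "kind": "binary", "levels": [["male", "1"], ["female", "2"]]},
    {"name": "steroid", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "antivirals", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "fatigue", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "malaise", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "anorexia", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "liver_big", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "liver_firm", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "spleen_palpable", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "spiders", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "ascites", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "varices", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]},
    {"name": "bilirubin", "kind": "continuous", "range": [0.3, 8]},
    {"name": "alk_phosphate", "kind": "continuous", "range": [26, 295]},
    {"name": "sgot", "kind": "continuous", "range": [14, 648]},
    {"name": "albumin", "kind": "continuous", "range": [2.1, 6.4]},
    {"name": "protime", "kind": "continuous", "range": [0, 100]},
    {"name": "histology", "kind": "binary", "levels": [["no", "1"], ["yes", "2"]]}
  ]
}
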