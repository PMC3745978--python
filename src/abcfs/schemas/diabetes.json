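{
  "name": "diabetes",
  "notes": "Pima Indians diabetes dialect: 8 clinical features, class last; 1 = positive diabetes test.",
  "has_header": false,
  "label": {"column": "class", "position": 8, "values": ["0", "1"], "positive": "1"},
  "columns": [
    {"name": "pregnancies", "kind": "discrete", "range": [0, 17]},
    {"name": "glucose", "kind": "continuous", "range": [0, 199]},
    {"name": "blood_pressure", "kind": "continuous", "range": [0, 122]},
    {"name": "skinfold_thickness", "kind": "continuous", "range": [0, 99]},
    {"name": "serum_insulin", "kind": "continuous", "range": [0, 846]},
    {"name": "bmi", "kind": "continuous", "range": [0, 67.1]},
    {"name": "pedigree", "kind": "continuous", "range": [0.078, 2.42]},
    {"name": "age", "kind": "continuous", "range": [21, 81]}
  ]
}
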