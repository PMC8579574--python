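{
  "name": "CRUISE",
  "paths": [
    {
      "conditions": [
        {"field": "mcv", "op": ">", "threshold": 71.25}
      ],
      "label": "BTT"
    },
    {
      "conditions": [
        {"field": "mcv", "op": ">", "threshold": 67.65},
        {"field": "mcv", "op": "<=", "threshold": 71.25},
        {"field": "hb", "op": "<=", "threshold": 11.15}
      ],
      "label": "BTT"
    },
    {
      "conditions": [
        {"field": "mcv", "op": ">", "threshold": 67.65},
        {"field": "mcv", "op": "<=", "threshold": 71.25},
        {"field": "hb", "op": ">", "threshold": 11.15}
      ],
      "label": "IDA"
    },
    {
      "conditions": [
        {"field": "mcv", "op": "<=", "threshold": 67.65},
        {"field": "hb", "op": ">", "threshold": 8.85}
      ],
      "label": "IDA"
    },
    {
      "conditions": [
        {"field": "mcv", "op": "<=", "threshold": 67.65},
        {"field": "hb", "op": "<=", "threshold": 8.85},
        {"field": "mchc", "op": "<=", "threshold": 30.32}
      ],
      "label": "BTT"
    },
    {
      "conditions": [
        {"field": "mcv", "op": "<=", "threshold": 67.65},
        {"field": "hb", "op": "<=", "threshold": 8.85},
        {"field": "mchc", "op": ">", "threshold": 30.32}
      ],
      "label": "IDA"
    }
  ]
}
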