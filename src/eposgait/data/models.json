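{
  "format_version": 1,
  "models": [
    {
      "label": "day2",
      "link": "logit",
      "intercept": -0.982,
      "terms": [
        {"name": "tct", "coef": 2.691},
        {"name": "mi", "coef": 2.083}
      ]
    },
    {
      "label": "day9",
      "link": "logit",
      "intercept": -2.226,
      "terms": [
        {"name": "tct", "coef": 3.629},
        {"name": "mi", "coef": 1.854}
      ]
    }
  ]
}
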