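{
  "provenance": "Interspecific OLS coefficients of ln(Y) = ln(a) + b*ln(IT) (Y and IT in mm, natural logs), from Cariveau et al. 2016 PLoS ONE 11(3):e0151482, Table 2. Proboscis and glossa share one scaling exponent across families (no family x IT interaction in the best model); prementum has a family-specific exponent.",
  "parts": [
    {
      "part": "proboscis",
      "a": {
        "Andrenidae": 1.06,
        "Apidae": 2.13,
        "Colletidae": 0.86,
        "Halictidae": 1.38,
        "Megachilidae": 1.87
      },
      "b": 0.96
    },
    {
      "part": "glossa",
      "a": {
        "Andrenidae": 0.23,
        "Apidae": 1.27,
        "Colletidae": 0.21,
        "Halictidae": 0.43,
        "Megachilidae": 1.16
      },
      "b": 1.04
    },
    {
      "part": "prementum",
      "a": {
        "Andrenidae": 0.88,
        "Apidae": 0.91,
        "Colletidae": 0.56,
        "Halictidae": 0.89,
        "Megachilidae": 0.77
      },
      "b": {
        "Andrenidae": 0.83,
        "Apidae": 0.73,
        "Colletidae": 1.14,
        "Halictidae": 1.04,
        "Megachilidae": 0.68
      }
    }
  ]
}
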