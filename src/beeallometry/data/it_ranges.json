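{
  "provenance": "Default per-family (min, max) species-mean intertegular distance in mm used for the extrapolation flag. SYNTHETIC defaults: representative ranges for North American members of each family, matching the synthetic study generator; override with the observed ranges of the coefficient-fitting data when available.",
  "ranges": {
    "Andrenidae": [1.2, 3.0],
    "Apidae": [1.0, 6.0],
    "Colletidae": [1.5, 3.5],
    "Halictidae": [0.8, 2.5],
    "Megachilidae": [1.5, 4.5]
  }
}
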