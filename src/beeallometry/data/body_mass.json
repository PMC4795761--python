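{
  "provenance": "Cane 1987, J. Kansas Entomol. Soc. 60:145-147: intertegular distance IT (mm) = 0.77 * (dry body mass mg)^0.405, R^2 = 0.97.",
  "c": 0.77,
  "e": 0.405
}
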