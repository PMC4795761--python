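{
  "provenance": "log10(distance km) = intercept + slope*log10(IT mm). typical_homing, max_homing and max_feeder_training are transcribed from Greenleaf et al. 2007 (Oecologia 153:589-596), Table 1; verify against that source before quantitative use. typical_foraging is a SYNTHETIC placeholder line (anchored to honey-bee-scale foraging distances), shipped so the metric is exercisable; replace with the published regression for real analyses.",
  "metrics": {
    "typical_homing": {"intercept": -1.643, "slope": 3.242},
    "max_homing": {"intercept": -1.363, "slope": 3.366},
    "max_feeder_training": {"intercept": -0.993, "slope": 2.788},
    "typical_foraging": {"intercept": -1.0, "slope": 2.5, "synthetic": true}
  }
}
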