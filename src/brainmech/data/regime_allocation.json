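{
  "pervin_chen_2009": {"quasi-static": 498, "high": 498},
  "pervin_chen_2011": {"quasi-static": 296, "high": 1604},
  "tamura_2007": {"quasi-static": 95, "intermediate": 95},
  "rashid_2014_tens": {"quasi-static": 90, "intermediate": 171},
  "rashid_2014_comp_b": {"quasi-static": 85, "intermediate": 85},
  "li_2019": {"quasi-static": 79, "intermediate": 79},
  "li_2020": {"quasi-static": 532, "intermediate": 168}
}
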