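{
  "A": "general",
  "B": "blood",
  "D": "digestive",
  "F": "eye",
  "H": "ear",
  "K": "circulatory",
  "L": "musculoskeletal",
  "N": "neurological",
  "P": "psychological",
  "R": "respiratory",
  "S": "skin",
  "T": "metabolic",
  "U": "urinary",
  "W": "pregnancy",
  "X": "gynaecological",
  "Y": "genital"
}
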