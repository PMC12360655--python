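{
 "montage": "biosemi64",
 "midline": [
  "C1",
  "C2",
  "C3",
  "C4",
  "C5",
  "C6",
  "CP1",
  "CP2",
  "CP3",
  "CP4",
  "CP5",
  "CP6",
  "CPz",
  "Cz",
  "FC1",
  "FC2",
  "FC3",
  "FC4",
  "FC5",
  "FC6",
  "FCz",
  "Fz",
  "Iz",
  "O1",
  "O2",
  "Oz",
  "P1",
  "P2",
  "P3",
  "P4",
  "P5",
  "P6",
  "PO3",
  "PO4",
  "PO7",
  "PO8",
  "POz",
  "Pz"
 ],
 "left": [
  "AF3",
  "AF7",
  "C1",
  "C3",
  "C5",
  "CP1",
  "CP3",
  "CP5",
  "F1",
  "F3",
  "F5",
  "FC1",
  "FC3",
  "FC5",
  "O1",
  "P1",
  "P3",
  "P5",
  "PO3",
  "PO7"
 ],
 "right": [
  "AF4",
  "AF8",
  "C2",
  "C4",
  "C6",
  "CP2",
  "CP4",
  "CP6",
  "F2",
  "F4",
  "F6",
  "FC2",
  "FC4",
  "FC6",
  "O2",
  "P2",
  "P4",
  "P6",
  "PO4",
  "PO8"
 ]
}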