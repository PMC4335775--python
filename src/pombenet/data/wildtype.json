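{
  "labels": ["Start", "SK", "Cdc2/Cdc13", "Ste9", "Rum1", "Slp1", "Cdc2/Cdc13*", "Wee1/Mik1", "Cdc25", "PP"],
  "W": [
    [-1,  0,  0,  0,  0,  0,  0,  0,  0,  0],
    [ 1, -1,  0,  0,  0,  0,  0,  0,  0,  0],
    [ 0,  0,  0, -1, -1, -1,  0,  0,  0,  0],
    [ 0, -1, -1,  0,  0,  0, -1,  0,  0,  1],
    [ 0, -1, -1,  0,  0,  0, -1,  0,  0,  1],
    [ 0,  0,  0,  0,  0, -1,  1,  0,  0,  0],
    [ 0,  0,  0, -1, -1, -1,  0, -1,  1,  0],
    [ 0,  0, -1,  0,  0,  0,  0,  0,  0,  1],
    [ 0,  0,  1,  0,  0,  0,  0,  0,  0, -1],
    [ 0,  0,  0,  0,  0,  1,  0,  0,  0, -1]
  ],
  "theta": [0, 0, -0.5, 0, 0, 0, 0.5, 0, 0, 0]
}
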