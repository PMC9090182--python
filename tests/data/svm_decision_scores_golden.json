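{
 "seed": 42,
 "shape": [
  40,
  50
 ],
 "signal_cols": 5,
 "signal_shift": 0.8,
 "regularization": 1.0,
 "decision_scores": [
  1.0002954228,
  1.0000861436,
  1.0004275041,
  1.0002218025,
  0.9997917404,
  1.0004072594,
  1.0977435891,
  2.2374058115,
  1.1728450004,
  1.0001575282,
  0.9998039289,
  1.4027478361,
  0.9999421861,
  0.9998653693,
  1.0001741504,
  1.3977405418,
  0.9994398194,
  1.000095282,
  1.5013030242,
  0.999758839,
  -0.9997970077,
  -0.9997304012,
  -0.9999357518,
  -0.9997997414,
  -1.0004355221,
  -1.476794903,
  -0.9999047187,
  -1.0002235241,
  -1.0000787278,
  -1.0000454314,
  -1.0002906547,
  -1.1029219741,
  -0.999916804,
  -1.8561836709,
  -0.9997175105,
  -1.0397738089,
  -0.999763537,
  -1.0002020049,
  -1.0004680393,
  -1.0856662572
 ]
}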