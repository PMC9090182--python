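{
 "seed": 2024,
 "n": 100,
 "kinds": [
  "linear",
  "independent",
  "quadratic",
  "sine"
 ],
 "values": [
  0.7316661747,
  0.32859426,
  0.8924756147,
  0.9374298383,
  0.8941078812,
  0.2731995214,
  0.8267463725,
  0.967548875,
  0.8859139685,
  0.2971957629,
  0.9895875212,
  0.9709505945,
  0.9031684121,
  0.3242441557,
  0.8570770536,
  0.8322475345,
  0.9765004688,
  0.3150841878,
  0.7979716506,
  0.8736986995
 ]
}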