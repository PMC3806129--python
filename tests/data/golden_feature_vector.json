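{
 "key": [
  "A",
  1
 ],
 "values": [
  0.0,
  1.0,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  0.03125,
  0.015625,
  0.015625,
  0.078125,
  0.0625,
  0.09375,
  0.09375,
  0.015625,
  0.03125,
  0.0625,
  0.046875,
  0.0625,
  0.0625,
  0.078125,
  0.046875,
  0.09375,
  0.0,
  0.015625,
  0.03125,
  0.0625,
  0.421875,
  0.25,
  0.328125,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  0.0,
  1.0,
  1.0,
  1.0,
  1.0,
  0.0,
  -1.0,
  0.0,
  -1.0,
  -1.0,
  -1.0,
  -1.0,
  -1.0,
  1.0,
  0.0,
  1.0,
  2.0,
  1.0,
  0.0,
  -3.0,
  -1.0,
  0.0,
  0.01801235,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  5.48,
  5.2,
  2.8,
  0.0,
  0.0,
  0.0,
  -1.0,
  1.0,
  0.0,
  1.0,
  -1.0,
  0.0,
  1.0,
  1.0,
  -1.0,
  -1.0,
  -1.0,
  1.0,
  1.0,
  -1.0,
  0.0,
  -1.0,
  0.0,
  -1.0,
  0.01613872,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  5.98,
  4.9,
  3.8,
  0.0,
  -5.0,
  -5.0,
  -3.0,
  -5.0,
  8.0,
  -4.0,
  -5.0,
  -5.0,
  -5.0,
  -5.0,
  -4.0,
  -5.0,
  -5.0,
  -5.0,
  -5.0,
  -5.0,
  -5.0,
  -5.0,
  -5.0,
  -5.0,
  0.67360319,
  1.0,
  0.0,
  0.0,
  0.0,
  0.0,
  5.07,
  5.5,
  2.5,
  0.0,
  0.0,
  0.0,
  -1.0,
  0.0,
  -1.0,
  1.0,
  3.0,
  3.0,
  -1.0,
  1.0,
  1.0,
  -3.0,
  -3.0,
  -1.0,
  0.0,
  -1.0,
  -1.0,
  -1.0,
  -1.0,
  -1.0,
  0.04451511,
  0.0,
  0.0,
  1.0,
  0.0,
  0.0,
  5.98,
  4.9,
  3.8,
  0.0,
  -1.0,
  1.0,
  1.0,
  -1.0,
  0.0,
  0.0,
  -3.0,
  1.0,
  -1.0,
  -1.0,
  3.0,
  -1.0,
  -1.0,
  -1.0,
  1.0,
  -1.0,
  -3.0,
  -5.0,
  -1.0,
  2.0,
  0.05679576,
  0.0,
  1.0,
  0.0,
  0.0,
  0.0,
  5.65,
  10.5,
  -3.5,
  0.0,
  0.01,
  0.3,
  0.11294118,
  0.02,
  0.0,
  1.0,
  0.11764706,
  0.0,
  1.0,
  0.11764706,
  3.22,
  9.74,
  5.80764706,
  5.2,
  12.3,
  8.12941176,
  -3.9,
  4.2,
  -0.35294118,
  0.01801235,
  0.66287485,
  0.10651388,
  0.35294118,
  0.29411765,
  0.35294118
 ]
}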