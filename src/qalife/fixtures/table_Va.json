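{
 "experiment": "Va",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 7733,
 "counts": {
  "0000": 1032,
  "0001": 422,
  "0010": 756,
  "0011": 594,
  "0100": 737,
  "0101": 51,
  "0110": 2121,
  "0111": 731,
  "1000": 88,
  "1001": 109,
  "1010": 132,
  "1011": 113,
  "1100": 99,
  "1101": 179,
  "1110": 186,
  "1111": 383
 },
 "provenance": "ibmqx4 published measurement table: complete model, unmutated group 1"
}
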