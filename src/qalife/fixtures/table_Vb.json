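{
 "experiment": "Vb",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 7796,
 "counts": {
  "0000": 1087,
  "0001": 414,
  "0010": 863,
  "0011": 696,
  "0100": 697,
  "0101": 44,
  "0110": 2076,
  "0111": 692,
  "1000": 107,
  "1001": 107,
  "1010": 134,
  "1011": 97,
  "1100": 99,
  "1101": 191,
  "1110": 188,
  "1111": 304
 },
 "provenance": "ibmqx4 published measurement table: complete model, unmutated group 2"
}
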