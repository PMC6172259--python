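{
 "experiment": "I",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 8093,
 "counts": {
  "0000": 1104,
  "0001": 338,
  "0010": 647,
  "0011": 542,
  "0100": 693,
  "0101": 355,
  "0110": 2687,
  "0111": 519,
  "1000": 104,
  "1001": 144,
  "1010": 114,
  "1011": 1,
  "1100": 99,
  "1101": 132,
  "1110": 261,
  "1111": 353
 },
 "provenance": "ibmqx4 published measurement table: two interacting individuals"
}
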