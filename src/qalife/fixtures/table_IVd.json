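{
 "experiment": "IVd",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 952,
 "counts": {
  "0000": 24,
  "0001": 16,
  "0010": 145,
  "0011": 1,
  "0100": 7,
  "0101": 19,
  "0110": 428,
  "0111": 23,
  "1000": 32,
  "1001": 159,
  "1010": 5,
  "1011": 2,
  "1100": 15,
  "1101": 64,
  "1110": 12,
  "1111": 0
 },
 "provenance": "ibmqx4 published measurement table: mutation family, both mutations"
}
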