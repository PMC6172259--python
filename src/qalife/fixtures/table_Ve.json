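{
 "experiment": "Ve",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 1024,
 "counts": {
  "0000": 219,
  "0001": 269,
  "0010": 62,
  "0011": 63,
  "0100": 74,
  "0101": 87,
  "0110": 44,
  "0111": 27,
  "1000": 27,
  "1001": 15,
  "1010": 15,
  "1011": 7,
  "1100": 28,
  "1101": 57,
  "1110": 12,
  "1111": 18
 },
 "provenance": "ibmqx4 published measurement table: complete model, sigma_x on g2 before interaction"
}
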