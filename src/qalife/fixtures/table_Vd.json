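{
 "experiment": "Vd",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 862,
 "counts": {
  "0000": 7,
  "0001": 6,
  "0010": 48,
  "0011": 45,
  "0100": 47,
  "0101": 5,
  "0110": 24,
  "0111": 61,
  "1000": 99,
  "1001": 89,
  "1010": 119,
  "1011": 122,
  "1100": 39,
  "1101": 48,
  "1110": 35,
  "1111": 68
 },
 "provenance": "ibmqx4 published measurement table: complete model, sigma_x on g1 before interaction"
}
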