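{
 "experiment": "IVc",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 1015,
 "counts": {
  "0000": 39,
  "0001": 28,
  "0010": 149,
  "0011": 7,
  "0100": 13,
  "0101": 34,
  "0110": 46,
  "0111": 3,
  "1000": 22,
  "1001": 137,
  "1010": 6,
  "1011": 2,
  "1100": 68,
  "1101": 444,
  "1110": 16,
  "1111": 1
 },
 "provenance": "ibmqx4 published measurement table: mutation family, sigma_x on g2 after second individual"
}
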