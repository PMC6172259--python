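{
 "experiment": "IVb",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 970,
 "counts": {
  "0000": 136,
  "0001": 14,
  "0010": 3,
  "0011": 14,
  "0100": 542,
  "0101": 32,
  "0110": 9,
  "0111": 6,
  "1000": 12,
  "1001": 29,
  "1010": 16,
  "1011": 122,
  "1100": 17,
  "1101": 12,
  "1110": 1,
  "1111": 5
 },
 "provenance": "ibmqx4 published measurement table: mutation family, sigma_x on g1 before replication"
}
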