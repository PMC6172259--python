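{
 "experiment": "II",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 8192,
 "counts": {
  "0000": 1491,
  "0001": 103,
  "0010": 42,
  "0011": 224,
  "0100": 387,
  "0101": 46,
  "0110": 31,
  "0111": 249,
  "1000": 67,
  "1001": 91,
  "1010": 108,
  "1011": 916,
  "1100": 149,
  "1101": 354,
  "1110": 439,
  "1111": 3495
 },
 "provenance": "ibmqx4 published measurement table: self-replication with discrete dissipation, z basis"
}
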