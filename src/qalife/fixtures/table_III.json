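{
 "experiment": "III",
 "basis": "x",
 "qubit_order": "g1p1g2p2",
 "shots": 7724,
 "counts": {
  "0000": 753,
  "0001": 246,
  "0010": 277,
  "0011": 52,
  "0100": 448,
  "0101": 747,
  "0110": 569,
  "0111": 513,
  "1000": 343,
  "1001": 493,
  "1010": 616,
  "1011": 177,
  "1100": 717,
  "1101": 679,
  "1110": 345,
  "1111": 749
 },
 "provenance": "ibmqx4 published measurement table: self-replication with discrete dissipation, x basis"
}
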