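{
 "experiment": "IVa",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 8192,
 "counts": {
  "0000": 1511,
  "0001": 121,
  "0010": 46,
  "0011": 201,
  "0100": 395,
  "0101": 86,
  "0110": 27,
  "0111": 213,
  "1000": 102,
  "1001": 192,
  "1010": 162,
  "1011": 984,
  "1100": 215,
  "1101": 635,
  "1110": 478,
  "1111": 2824
 },
 "provenance": "ibmqx4 published measurement table: mutation family, unmutated group"
}
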