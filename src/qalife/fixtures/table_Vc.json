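{
 "experiment": "Vc",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 7778,
 "counts": {
  "0000": 1046,
  "0001": 445,
  "0010": 871,
  "0011": 631,
  "0100": 723,
  "0101": 46,
  "0110": 2056,
  "0111": 634,
  "1000": 111,
  "1001": 114,
  "1010": 154,
  "1011": 148,
  "1100": 97,
  "1101": 162,
  "1110": 192,
  "1111": 348
 },
 "provenance": "ibmqx4 published measurement table: complete model, unmutated group 3"
}
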