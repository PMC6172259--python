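{
 "experiment": "Vf",
 "basis": "z",
 "qubit_order": "g1p1g2p2",
 "shots": 1024,
 "counts": {
  "0000": 58,
  "0001": 42,
  "0010": 56,
  "0011": 24,
  "0100": 83,
  "0101": 65,
  "0110": 48,
  "0111": 21,
  "1000": 89,
  "1001": 66,
  "1010": 75,
  "1011": 42,
  "1100": 232,
  "1101": 55,
  "1110": 43,
  "1111": 25
 },
 "provenance": "ibmqx4 published measurement table: complete model, both mutations before interaction"
}
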