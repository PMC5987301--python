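# Toy two-module interconnection (cascade x inverter).
modules:
  A: ../example1_A.bnetio
  B: ../example2_B.bnetio
wiring:
  - A.u <- B.w
  - B.v <- A.y
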