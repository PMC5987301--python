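# Mammalian cell cycle x circadian clock: u = BMAL, v = Cdc20 & CycB.
modules:
  A: ../mammal_cc10.bnetio
  B: ../clock7.bnetio
wiring:
  - A.u <- B.bmal
  - B.v <- A.mitosis
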