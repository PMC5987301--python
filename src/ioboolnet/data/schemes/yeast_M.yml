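# Yeast cell cycle x cell size: u = Cln3F, v = Swi5 & Cdc20 (M phase).
modules:
  A: ../yeast_cc11.bnetio
  B: ../cellsize8.bnetio
wiring:
  - A.u <- B.cln3f
  - B.v <- A.mphase
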