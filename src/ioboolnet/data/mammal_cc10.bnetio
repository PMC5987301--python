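# Ten-variable mammalian cell-cycle module (logical rules of Faure et al.
# 2006, with cyclin E additionally gated by the clock input u = BMAL acting
# in G1).  Variable order fixes the printed bit strings:
# (CycD, Rb, E2F, CycE, CycA, p27, Cdc20, Cdh1, Ubc, CycB).
# The output flags mitosis, Cdc20 & CycB.
module mammal_cc10
inputs: u
CycD* = CycD
Rb* = (!CycD & !CycE & !CycA & !CycB) | (p27 & !CycD & !CycB)
E2F* = (!Rb & !CycA & !CycB) | (p27 & !Rb & !CycB)
CycE* = !u & (E2F & !Rb)
CycA* = (E2F & !Rb & !Cdc20 & !(Cdh1 & Ubc)) | (CycA & !Rb & !Cdc20 & !(Cdh1 & Ubc))
p27* = (!CycD & !CycE & !CycA & !CycB) | (p27 & !(CycE & CycA) & !CycB & !CycD)
Cdc20* = CycB
Cdh1* = (!CycA & !CycB) | Cdc20 | (p27 & !CycB)
Ubc* = !Cdh1 | (Cdh1 & Ubc & (Cdc20 | CycA | CycB))
CycB* = !Cdc20 & !Cdh1
output mitosis = Cdc20 & CycB
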