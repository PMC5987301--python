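# Eleven-variable budding-yeast cell-cycle module (threshold network of
# Li et al. 2004 written out as Boolean rules: equal +1/-1 weights, next
# value 1 on positive net input, 0 on negative, and on zero net input the
# current value is kept except for the self-degrading nodes START, Cln1,
# Swi5, Cdc20 and Mcm, which decay to 0).  START is driven by the external
# input u instead of a transient size signal.  Variable order fixes the
# printed bit strings:
# (START, MBF, SBF, Cln1, Cdh1, Swi5, Cdc20, Clb5, Sic1, Clb1, Mcm).
# The default output flags M phase, Swi5 & Cdc20; the S- and G1-phase
# output variants (Clb5, Cdh1 & Sic1) are attached by the interconnection
# scheme builders.
module yeast_cc11
inputs: u
START* = u
MBF* = (START & !Clb1) | (MBF & (START | !Clb1))
SBF* = (START & !Clb1) | (SBF & (START | !Clb1))
Cln1* = SBF
Cdh1* = (Cdc20 & !Cln1 & !Clb5 & !Clb1) | (Cdh1 & ((!Cdc20 & !Cln1 & !Clb5 & !Clb1) | (Cdc20 & ((Cln1 & !Clb5 & !Clb1) | (!Cln1 & Clb5 & !Clb1) | (!Cln1 & !Clb5 & Clb1)))))
Swi5* = (Cdc20 & Mcm) | ((Cdc20 | Mcm) & !Clb1)
Cdc20* = Clb1 | Mcm
Clb5* = (MBF & !Sic1 & !Cdc20) | (Clb5 & ((!MBF & !Sic1 & !Cdc20) | (MBF & ((Sic1 & !Cdc20) | (!Sic1 & Cdc20)))))
Sic1* = (((Swi5 & !Cdc20) | (!Swi5 & Cdc20)) & (!Cln1 & !Clb5 & !Clb1)) | ((Swi5 & Cdc20) & ((!Cln1 & !Clb5 & !Clb1) | (Cln1 & !Clb5 & !Clb1) | (!Cln1 & Clb5 & !Clb1) | (!Cln1 & !Clb5 & Clb1))) | (Sic1 & (((!Swi5 & !Cdc20) & (!Cln1 & !Clb5 & !Clb1)) | (((Swi5 & !Cdc20) | (!Swi5 & Cdc20)) & ((Cln1 & !Clb5 & !Clb1) | (!Cln1 & Clb5 & !Clb1) | (!Cln1 & !Clb5 & Clb1))) | ((Swi5 & Cdc20) & ((Cln1 & Clb5 & !Clb1) | (Cln1 & !Clb5 & Clb1) | (!Cln1 & Clb5 & Clb1)))))
Clb1* = (((Clb5 & !Mcm) | (!Clb5 & Mcm)) & (!Cdh1 & !Cdc20 & !Sic1)) | ((Clb5 & Mcm) & ((!Cdh1 & !Cdc20 & !Sic1) | (Cdh1 & !Cdc20 & !Sic1) | (!Cdh1 & Cdc20 & !Sic1) | (!Cdh1 & !Cdc20 & Sic1))) | (Clb1 & (((!Clb5 & !Mcm) & (!Cdh1 & !Cdc20 & !Sic1)) | (((Clb5 & !Mcm) | (!Clb5 & Mcm)) & ((Cdh1 & !Cdc20 & !Sic1) | (!Cdh1 & Cdc20 & !Sic1) | (!Cdh1 & !Cdc20 & Sic1))) | ((Clb5 & Mcm) & ((Cdh1 & Cdc20 & !Sic1) | (Cdh1 & !Cdc20 & Sic1) | (!Cdh1 & Cdc20 & Sic1)))))
Mcm* = Clb5 | Clb1
output mphase = Swi5 & Cdc20
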