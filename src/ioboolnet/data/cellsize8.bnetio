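# Budding-yeast cell-size module: the chaperone Ydj1 is shared between a
# growth-rate-dependent protein Prot and cyclin Cln3, which must be folded
# (Cln3F) to trigger START.  The input v is the growth-rate signal; the
# output exposes folded Cln3.
module cellsize8
inputs: v
Ydj1* = YP | YC | !(Prot & Cln3)
YP* = Ydj1 & Prot
YC* = Ydj1 & Cln3
Prot* = v
ProtF* = YP
Cln3* = !Whi3
Cln3F* = YC
Whi3* = v
output cln3f = Cln3F
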