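# Two-variable single-input single-output cascade u -> x1 -> x2.
module example1_A
inputs: u
x1* = u
x2* = x1
output y = x2
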