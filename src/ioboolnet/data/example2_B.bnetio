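# One-variable single-input single-output inverter.
module example2_B
inputs: v
y1* = !v
output w = y1
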