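# Synthetic two-variable SISO module.  Constructed so that under both
# inputs the SCC decomposition groups {00,10} and {01,11}; the meet of the
# two per-input SCC partitions is therefore {{*0},{*1}} and is already
# output-constant for h(x) = x2.
module example4_A
inputs: u
x1* = !x1
x2* = !u & x2
output y = x2
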