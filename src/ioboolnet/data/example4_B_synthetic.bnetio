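# Synthetic two-variable SISO module.  Constructed so that every per-input
# transition graph is acyclic with singleton SCCs only; the meet of the
# per-input SCC partitions is the partition into the four singletons.
module example4_B
inputs: u
y1* = u
y2* = y1
output w = y1
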