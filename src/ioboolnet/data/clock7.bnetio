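# Seven-variable circadian clock module.  The input v models transcription
# shutdown during mitosis (v = 1 silences all mRNAs); the output exposes BMAL.
module clock7
inputs: v
BMAL* = !PCnuc
mPER* = !v & BMAL
mCRY* = !v & BMAL
pPER* = mPER
pCRY* = mCRY
PC* = pPER & pCRY
PCnuc* = PC
output bmal = BMAL
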