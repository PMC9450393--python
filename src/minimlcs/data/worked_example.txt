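# three example DNA sequences; their unique MLCS is ACGTC
AACGTCGT
CGACGTCC
GACCGTCT
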