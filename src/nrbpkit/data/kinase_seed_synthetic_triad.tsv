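# triad name <TAB> 0-based seed alignment column (synthetic seed)
beta3_K	15
HRD_D	30
DFG_D	45
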