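# 11 evenly spread polymerization foci (LTP expansion)
command: run
foci: evenly
n_foci: 11
duration: 160.0
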