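command: run
foci: near_neck
n_foci: 1
duration: 160.0
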