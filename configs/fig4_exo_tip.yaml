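command: exo
mode: tip_focus
duration: 30.0
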