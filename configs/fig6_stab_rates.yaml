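# PSD stabilization rate sweep (delta_psd in um/s; 0 = control)
command: stabilize
rates: [0.0, 0.00025, 0.0005, 0.001]
duration: 420.0
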