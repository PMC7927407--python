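{"k1": 1.2, "k3": 1.2, "b1": 0.75, "b2": 0.75, "alpha": 1.0}
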