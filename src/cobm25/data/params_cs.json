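{"k1": 3.59, "k3": 1.3, "b1": 0.84, "b2": 1.0, "alpha": 4.0}
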