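{"label": "pde2d", "A": "1.45", "B": ".0051", "Gamma1": "0.0004", "N": "0.032",
 "M": "0.01", "C": "0.044", "G": "0", "D0": "0.013", "D": "1", "Gamma": "33.6",
 "x_scale": "24.95", "t_scale": ".038", "t_scale_alt": ".0377"}
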