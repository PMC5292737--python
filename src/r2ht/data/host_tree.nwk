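(rossius:22.8,((benazzii:2,maretimi:2):15,(grandii_grandii:15.4,atticus:15.4):1.6):5.8);
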