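species,C01,C02,C03
Species 02,1,1,1
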