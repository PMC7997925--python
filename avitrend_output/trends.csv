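species,euring_code,base_year,trend,se,class,note
Species 02,10020,1980,1.0206532948095035,0.0027568957255347227,Moderate increase,
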