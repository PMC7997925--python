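species,euring_code,base_year,trend,se,class
Species 02,10020,1990,1.018963983970191,0.0072086831643825506,Moderate increase
Species 02,10020,1990,1.018963983970191,0.0072086831643825506,Moderate increase
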