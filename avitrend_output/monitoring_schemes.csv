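country,collaborators,scheme_name,count_method,plot_selection,initial_year,end_year,region,reference
C01,10,C01 common bird monitoring,point counts,stratified random,1980,1999,West Europe,synthetic scheme
C02,10,C02 common bird monitoring,point counts,stratified random,1980,1999,West Europe,synthetic scheme
C03,10,C03 common bird monitoring,point counts,stratified random,1986,1999,West Europe,synthetic scheme
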