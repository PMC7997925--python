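species,euring_code,year,index,se
Species 02,10020,1980,100.0,0.0
Species 02,10020,1981,103.15837938850758,10.897403049540028
Species 02,10020,1982,94.24139072133674,10.208853131148809
Species 02,10020,1983,113.53160269682571,11.565287635571332
Species 02,10020,1984,118.8669095923785,12.488688442753592
Species 02,10020,1985,101.62386749292568,10.658001939874566
Species 02,10020,1986,104.18209481754157,11.152894294384295
Species 02,10020,1987,119.2752069524676,11.958031888879216
Species 02,10020,1988,120.42882723247546,13.316618116315922
Species 02,10020,1989,124.97588538407693,14.118751806394329
Species 02,10020,1990,116.8408695045521,11.653777348436952
Species 02,10020,1991,125.2008557253398,12.827380764068225
Species 02,10020,1992,127.47822344416988,12.924237820703807
Species 02,10020,1993,133.08882248418337,13.235281841756938
Species 02,10020,1994,140.69083504096633,13.780720894277717
Species 02,10020,1995,143.8435820554591,14.043127102256184
Species 02,10020,1996,132.41683036368394,13.235483161955244
Species 02,10020,1997,147.77067620544352,14.610736439020306
Species 02,10020,1998,131.0156157670047,12.808941738449093
Species 02,10020,1999,146.50827733218384,14.331870981162059
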