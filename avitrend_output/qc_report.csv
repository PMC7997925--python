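scheme_species,flag,rule,where,value
C01/Species 01,0,site above 10% of national count,C01-S004,0.10886850152905199
C01/Species 01,1,site above 10% of national count,C01-S005,0.1577981651376147
C01/Species 01,2,site above 10% of national count,C01-S009,0.12966360856269113
C01/Species 01,3,site above 10% of national count,C01-S010,0.200203873598369
C02/Species 01,0,site above 10% of national count,C02-S003,0.10995099083741743
C02/Species 01,1,site above 10% of national count,C02-S006,0.1350948220754315
C02/Species 01,2,site above 10% of national count,C02-S008,0.1570424035797997
C02/Species 01,3,site above 10% of national count,C02-S009,0.1238014063498828
C02/Species 01,4,site above 10% of national count,C02-S010,0.16322181973151503
C03/Species 01,0,site above 10% of national count,C03-S004,0.12908541609447954
C03/Species 01,1,site above 10% of national count,C03-S005,0.10931062894809118
C03/Species 01,2,site above 10% of national count,C03-S006,0.12936006591595717
C03/Species 01,3,site above 10% of national count,C03-S008,0.1112331776984345
C03/Species 01,4,site above 10% of national count,C03-S010,0.1524306509200769
C01/Species 02,0,site above 10% of national count,C01-S005,0.16670084068074636
C01/Species 02,1,site above 10% of national count,C01-S009,0.1377896247693254
C01/Species 02,2,site above 10% of national count,C01-S010,0.19479188025425467
C02/Species 02,0,site above 10% of national count,C02-S006,0.1481248690551016
C02/Species 02,1,site above 10% of national count,C02-S008,0.17578043159438508
C02/Species 02,2,site above 10% of national count,C02-S009,0.10475591870940708
C02/Species 02,3,site above 10% of national count,C02-S010,0.16488581604860675
C03/Species 02,0,site above 10% of national count,C03-S004,0.13191712562286914
C03/Species 02,1,site above 10% of national count,C03-S005,0.11041174927878311
C03/Species 02,2,site above 10% of national count,C03-S006,0.12168895882507212
C03/Species 02,3,site above 10% of national count,C03-S008,0.12457382638342512
C03/Species 02,4,site above 10% of national count,C03-S009,0.1001835824809861
C03/Species 02,5,site above 10% of national count,C03-S010,0.11487018095987411
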