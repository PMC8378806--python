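year,hs_group,product,value_usd,volume_kg
2014,0201,fresh,65650,5593
2015,0201,fresh,64185,11746
2016,0201,fresh,202560,126388
2017,0201,fresh,315230,246277
2018,0201,fresh,49388,27162
2014,0202,frozen,9834838,7268323
2015,0202,frozen,6794863,4202084
2016,0202,frozen,12573417,9660799
2017,0202,frozen,13024312,9271383
2018,0202,frozen,13279098,9976993
2014,0206,offal,31783778,30627543
2015,0206,offal,32350555,36485517
2016,0206,offal,27335381,31375020
2017,0206,offal,31884577,33369587
2018,0206,offal,37820374,34024121
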