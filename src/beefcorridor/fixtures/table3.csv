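origin,hs_group,product,value_usd,volume_kg
France,0201,fresh,970,128
Italy,0201,fresh,6241,227
Luxembourg,0201,fresh,2036,54
South Africa,0201,fresh,4584,521
United Kingdom,0201,fresh,32427,25867
USA,0201,fresh,3057,356
Botswana,0201,fresh,73,9
Belgium,0202,frozen,4202168,3291955
Brazil,0202,frozen,516768,316789
Canada,0202,frozen,23390,2377
France,0202,frozen,17203,3294
Germany,0202,frozen,182664,25222
Ireland,0202,frozen,3379239,2798606
Italy,0202,frozen,655974,847603
Netherlands,0202,frozen,1264554,829678
Poland,0202,frozen,523621,572447
India,0202,frozen,641357,317000
South Africa,0202,frozen,316429,47322
Spain,0202,frozen,166833,33381
United Kingdom,0202,frozen,1067253,844544
USA,0202,frozen,289259,16475
Kenya,0202,frozen,20627,2300
Ukraine,0202,frozen,11759,28000
Argentina,0206,offal,327316,318763
Austria,0206,offal,31495,25600
Belgium,0206,offal,4730824,3806161
Brazil,0206,offal,5039315,3650443
Croatia,0206,offal,77479,125000
Cyprus,0206,offal,22699,24660
Estonia,0206,offal,29142,78000
France,0206,offal,484377,226367
Germany,0206,offal,2649137,3579817
Greece,0206,offal,13762,24807
Iceland,0206,offal,75490,98780
Ireland,0206,offal,8114371,6761650
Italy,0206,offal,2954252,3229267
Other Asia nes,0206,offal,3746,5400
Netherlands,0206,offal,6619382,5387134
Norway,0206,offal,228685,248530
Paraguay,0206,offal,84837,83997
Poland,0206,offal,742650,904017
Russian Federation,0206,offal,854487,1053160
Serbia,0206,offal,76538,126580
South Africa,0206,offal,2233,457
Spain,0206,offal,1614992,1499750
Sweden,0206,offal,86789,101000
United Kingdom,0206,offal,2795969,2463223
USA,0206,offal,144800,174058
Ukraine,0206,offal,15607,27500
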