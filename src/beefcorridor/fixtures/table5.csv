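item,value
ex_abattoir_cfa_per_kg,1000
transport_share,0.10
transport_cfa_per_kg,100
informal_share,0.01
informal_cfa_per_kg,11
landed_cfa_per_kg,1111
ghana_butcher_cfa_per_kg,1416
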