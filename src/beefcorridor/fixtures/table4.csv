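item,value
fob_usd_per_kg,1.11
freight_total_eur,3500
freight_load_kg,25000
usd_per_eur,1.18
tariff_rate,0.35
trader_margin_low,0.05
trader_margin_high,0.08
wholesale_usd_high_margin,1.86
wholesale_usd_low_margin,1.81
wholesale_cfa_high_margin,1073
wholesale_cfa_low_margin,1043
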