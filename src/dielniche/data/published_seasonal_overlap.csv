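species,delta,ci_low,ci_high,p_value_printed
forest_musk_deer,0.71,0.61,0.80,0.15
chinese_goral,0.83,0.71,0.92,0.44
reeves_muntjac,0.83,0.73,0.90,0.23
siberian_roe_deer,0.86,0.83,0.89,<0.01
wild_boar,0.77,0.71,0.83,<0.01
sheep,0.55,0.44,0.64,<0.01
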