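species_a,species_b,season,partition,delta,ci_low,ci_high,p_value_printed
sheep,forest_musk_deer,cold,wild-domestic,0.25,0.15,0.36,<0.01
sheep,chinese_goral,cold,wild-domestic,0.46,0.34,0.59,<0.01
sheep,reeves_muntjac,cold,wild-domestic,0.40,0.30,0.49,<0.01
sheep,siberian_roe_deer,cold,wild-domestic,0.43,0.25,0.61,<0.01
sheep,wild_boar,cold,wild-domestic,0.57,0.49,0.66,<0.01
forest_musk_deer,chinese_goral,cold,wild-wild,0.54,0.42,0.65,<0.01
forest_musk_deer,reeves_muntjac,cold,wild-wild,0.78,0.68,0.88,0.02
forest_musk_deer,siberian_roe_deer,cold,wild-wild,0.68,0.57,0.79,0.10
forest_musk_deer,wild_boar,cold,wild-wild,0.62,0.51,0.72,<0.01
chinese_goral,reeves_muntjac,cold,wild-wild,0.62,0.55,0.76,<0.01
chinese_goral,siberian_roe_deer,cold,wild-wild,0.61,0.42,0.78,0.02
chinese_goral,wild_boar,cold,wild-wild,0.75,0.65,0.85,<0.01
reeves_muntjac,siberian_roe_deer,cold,wild-wild,0.70,0.58,0.80,0.11
reeves_muntjac,wild_boar,cold,wild-wild,0.81,0.68,0.91,<0.01
siberian_roe_deer,wild_boar,cold,wild-wild,0.67,0.47,0.85,0.27
sheep,forest_musk_deer,warm,wild-domestic,0.37,0.22,0.52,<0.01
sheep,chinese_goral,warm,wild-domestic,0.54,0.39,0.59,<0.01
sheep,reeves_muntjac,warm,wild-domestic,0.54,0.42,0.65,<0.01
sheep,siberian_roe_deer,warm,wild-domestic,0.51,0.38,0.64,<0.01
sheep,wild_boar,warm,wild-domestic,0.64,0.50,0.77,<0.01
forest_musk_deer,chinese_goral,warm,wild-wild,0.62,0.49,0.76,<0.01
forest_musk_deer,reeves_muntjac,warm,wild-wild,0.68,0.57,0.79,<0.01
forest_musk_deer,siberian_roe_deer,warm,wild-wild,0.83,0.70,0.94,0.34
forest_musk_deer,wild_boar,warm,wild-wild,0.63,0.50,0.74,<0.01
chinese_goral,reeves_muntjac,warm,wild-wild,0.85,0.78,0.92,0.11
chinese_goral,siberian_roe_deer,warm,wild-wild,0.70,0.61,0.80,<0.01
chinese_goral,wild_boar,warm,wild-wild,0.82,0.73,0.89,0.02
reeves_muntjac,siberian_roe_deer,warm,wild-wild,0.77,0.69,0.85,<0.01
reeves_muntjac,wild_boar,warm,wild-wild,0.83,0.79,0.88,<0.01
siberian_roe_deer,wild_boar,warm,wild-wild,0.72,0.65,0.80,<0.01
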