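species,common_name,independent_events
forest_musk_deer,Forest musk deer,87
chinese_goral,Chinese goral,162
reeves_muntjac,Reeve's muntjac,794
siberian_roe_deer,Siberian roe deer,106
wild_boar,Wild boar,2588
sheep,Domestic sheep,123
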