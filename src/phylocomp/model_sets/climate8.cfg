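# Candidate structural equation models linking seasonality (latitude as
# proxy) to brumation duration, breeding-season length and the formation
# of dense breeding aggregations.  Reconstruction of the described model
# family; edit freely -- the analysis only requires a consistent node set.

[m1_full_chain]
brumation <- latitude
breeding_season <- brumation
aggregation <- breeding_season

[m2_chain_plus_direct_brumation]
brumation <- latitude
breeding_season <- brumation
aggregation <- breeding_season + brumation

[m3_brumation_drives_both]
brumation <- latitude
breeding_season <- brumation
aggregation <- brumation

[m4_latitude_direct_season]
brumation <- latitude
breeding_season <- latitude
aggregation <- breeding_season

[m5_dual_season_sources]
brumation <- latitude
breeding_season <- brumation + latitude
aggregation <- breeding_season

[m6_latitude_direct_aggregation]
brumation <- latitude
breeding_season <- brumation
aggregation <- latitude

[m7_chain_plus_direct_latitude]
brumation <- latitude
breeding_season <- brumation
aggregation <- breeding_season + latitude

[m8_all_direct]
brumation <- latitude
breeding_season <- brumation + latitude
aggregation <- breeding_season + brumation + latitude
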