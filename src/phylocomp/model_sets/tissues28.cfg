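# Candidate structural equation models for direct and indirect effects
# of brumation duration on the digestive tract, fat stores, brain,
# testes and hindlimb muscles.  Reconstruction of the described
# 28-model family (mediation via gut and/or fat; brain-testis
# directionality); body size enters as a control at fit time, not as
# a node here.

[t01_bf_direct_none]
gut <- brumation
fat <- brumation
brain <- brumation
testes <- brumation
hindlimb <- brumation

[t02_bf_direct_b2t]
gut <- brumation
fat <- brumation
brain <- brumation
testes <- brumation + brain
hindlimb <- brumation

[t03_bf_direct_t2b]
gut <- brumation
fat <- brumation
brain <- brumation + testes
testes <- brumation
hindlimb <- brumation

[t04_bf_fat_none]
gut <- brumation
fat <- brumation
brain <- fat
testes <- fat
hindlimb <- fat

[t05_bf_fat_b2t]
gut <- brumation
fat <- brumation
brain <- fat
testes <- fat + brain
hindlimb <- fat

[t06_bf_fat_t2b]
gut <- brumation
fat <- brumation
brain <- fat + testes
testes <- fat
hindlimb <- fat

[t07_bf_both_none]
gut <- brumation
fat <- brumation
brain <- brumation + fat
testes <- brumation + fat
hindlimb <- brumation + fat

[t08_bf_both_b2t]
gut <- brumation
fat <- brumation
brain <- brumation + fat
testes <- brumation + fat + brain
hindlimb <- brumation + fat

[t09_bf_both_t2b]
gut <- brumation
fat <- brumation
brain <- brumation + fat + testes
testes <- brumation + fat
hindlimb <- brumation + fat

[t10_gf_direct_none]
gut <- brumation
fat <- gut
brain <- brumation
testes <- brumation
hindlimb <- brumation

[t11_gf_direct_b2t]
gut <- brumation
fat <- gut
brain <- brumation
testes <- brumation + brain
hindlimb <- brumation

[t12_gf_direct_t2b]
gut <- brumation
fat <- gut
brain <- brumation + testes
testes <- brumation
hindlimb <- brumation

[t13_gf_fat_none]
gut <- brumation
fat <- gut
brain <- fat
testes <- fat
hindlimb <- fat

[t14_gf_fat_b2t]
gut <- brumation
fat <- gut
brain <- fat
testes <- fat + brain
hindlimb <- fat

[t15_gf_fat_t2b]
gut <- brumation
fat <- gut
brain <- fat + testes
testes <- fat
hindlimb <- fat

[t16_gf_both_none]
gut <- brumation
fat <- gut
brain <- brumation + fat
testes <- brumation + fat
hindlimb <- brumation + fat

[t17_gf_both_b2t]
gut <- brumation
fat <- gut
brain <- brumation + fat
testes <- brumation + fat + brain
hindlimb <- brumation + fat

[t18_gf_both_t2b]
gut <- brumation
fat <- gut
brain <- brumation + fat + testes
testes <- brumation + fat
hindlimb <- brumation + fat

[t19_bgf_direct_none]
gut <- brumation
fat <- brumation + gut
brain <- brumation
testes <- brumation
hindlimb <- brumation

[t20_bgf_direct_b2t]
gut <- brumation
fat <- brumation + gut
brain <- brumation
testes <- brumation + brain
hindlimb <- brumation

[t21_bgf_direct_t2b]
gut <- brumation
fat <- brumation + gut
brain <- brumation + testes
testes <- brumation
hindlimb <- brumation

[t22_bgf_fat_none]
gut <- brumation
fat <- brumation + gut
brain <- fat
testes <- fat
hindlimb <- fat

[t23_bgf_fat_b2t]
gut <- brumation
fat <- brumation + gut
brain <- fat
testes <- fat + brain
hindlimb <- fat

[t24_bgf_fat_t2b]
gut <- brumation
fat <- brumation + gut
brain <- fat + testes
testes <- fat
hindlimb <- fat

[t25_bgf_both_none]
gut <- brumation
fat <- brumation + gut
brain <- brumation + fat
testes <- brumation + fat
hindlimb <- brumation + fat

[t26_bgf_both_b2t]
gut <- brumation
fat <- brumation + gut
brain <- brumation + fat
testes <- brumation + fat + brain
hindlimb <- brumation + fat

[t27_bgf_both_t2b]
gut <- brumation
fat <- brumation + gut
brain <- brumation + fat + testes
testes <- brumation + fat
hindlimb <- brumation + fat

[t28_gutfat_organs]
gut <- brumation
fat <- brumation + gut
brain <- gut + fat
testes <- gut + fat
hindlimb <- gut + fat
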