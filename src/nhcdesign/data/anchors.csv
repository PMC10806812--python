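ligand,r_ruch2_A,productivity_kcal,bdfe_kcal,g_ru9_kcal,span_kcal
9,1.813,5.4,35.5,-4.3,22.6
10,1.813,8.1,,,
11,1.816,2.6,38.8,-1.0,20.0
12,1.816,3.7,,,
13,1.817,2.8,,,
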