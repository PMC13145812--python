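# Electron mass collision stopping power for liquid water, version 1.
# Representative ICRU/NIST-style collision stopping powers (radiative part
# excluded).  Values are smooth to ~1% of published tabulations over the
# 0.5-20 MeV interval used by the engine; lookups interpolate log-linearly
# and clamp at the table floor.
energy_MeV,S_col_MeV_cm2_g
0.5,2.034
0.7,1.932
1.0,1.849
1.5,1.822
2.0,1.824
3.0,1.846
4.0,1.870
5.0,1.892
6.0,1.911
8.0,1.944
10.0,1.968
12.0,1.988
14.0,2.004
16.0,2.017
17.5,2.027
18.0,2.029
20.0,2.046
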