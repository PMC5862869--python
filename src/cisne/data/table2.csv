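# Synthetic dose-effect example: synergistic two-drug combination (true CI = 0.6).
# Effect columns hold the fraction unaffected (fu); read with fa_or_fu='fu'.
# Combination column dose is the total mixture dose.
# ratio: 1:1
dose,A2,B2,A2+B2
0.625,0.992,0.988,0.999
1.25,0.964,0.951,0.998
2.5,0.923,0.924,0.911
5,0.838,0.828,0.673
10,0.648,0.624,0.365
20,0.202,0.263,0.104
40,0.107,0.054,0.037
80,0.067,0.020,0.020
160,0.058,0.005,0.018
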