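# Synthetic dose-effect example: additive two-drug combination (true CI = 1).
# Effect columns hold the fraction unaffected (fu); read with fa_or_fu='fu'.
# Combination column dose is the total mixture dose.
# ratio: 1:1
dose,A1,B1,A1+B1
0.625,0.999,0.997,0.956
1.25,0.992,0.970,0.933
2.5,0.963,0.959,0.919
5,0.789,0.782,0.745
10,0.469,0.484,0.559
20,0.182,0.221,0.134
40,0.115,0.045,0.047
80,0.046,0.009,0.003
160,0.012,0.005,0.003
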