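abbreviation,W,WW,H,D,DH,suspect,note
ALP,926,2770,81.4698,2845,24.1903,,
AMT,882,2780,70.7087,2581,26.2091,H,printed Harary disagrees with the recomputed value for the graph that reproduces this row's W/WW/D/DH
AMX,1075,3398,85.8329,3291,25.4936,W;WW;H;D;DH,row inconsistent with the all-hydrogen row of the same structure
BSP,2514,13028,102.7360,3764,57.3198,,
CLM,995,3194,78.0429,2861,28.6732,,
DSP,882,2780,70.7087,2581,26.2091,W;WW;H;D;DH,duplicates the 21-vertex AMT/IMP row; the 20-vertex H-suppressed skeleton cannot attain it
DVF,897,2846,71.6540,1329,46.9409,W;WW;H;D;DH,row inconsistent with the all-hydrogen row of the same structure
DZM,726,2077,69.4905,1901,24.9069,,
FLX,1292,4946,77.8563,1772,54.1895,W;WW;H;D;DH,matches the skeleton only if the N-H hydrogen is kept as a 23rd vertex
IMP,882,2780,70.7087,2581,26.2091,H,printed Harary disagrees with the recomputed value for the graph that reproduces this row's W/WW/D/DH
LRZ,1034,3076,86.5452,2601,33.9740,W;WW;H;D;DH,row inconsistent with the all-hydrogen row of the same structure
NTP,882,2780,70.7087,2581,26.2091,W;WW;H;D;DH,duplicates the 21-vertex AMT/IMP row; the 20-vertex H-suppressed skeleton cannot attain it
OZP,928,2731,80.6476,2362,30.8960,W;WW;H;D;DH,row inconsistent with the all-hydrogen row of the same structure
PTP,882,2780,70.7087,2581,26.2091,W;WW;H;D;DH,duplicates the 21-vertex AMT/IMP row; the 20-vertex H-suppressed skeleton cannot attain it
TMP,979,3081,78.4611,2808,30.3429,,
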