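abbreviation,W,WW,H,D,DH,suspect,note
ALP,2936,10289,168.8604,7858,68.2119,,
AMT,5252,20371,239.9619,12117,126.6943,,
AMX,3564,12697,193.5572,9689,78.4991,,
BSP,12709,69193,366.6186,18125,244.3614,,
CLM,5462,21023,250.8310,12557,134.2503,,
DSP,4538,16736,226.4617,10943,114.0553,,
DVF,4836,17076,248.9564,7008,179.4176,,
DZM,2497,8380,154.1603,5741,71.3523,,
FLX,4433,17760,198.7027,6065,148.3364,,
IMP,5462,21023,250.8310,12557,134.2503,,
LRZ,2142,7027,139.4702,5038,62.4229,,
NTP,4346,16147,216.0927,10521,106.9993,,
OZP,2142,7027,139.4702,5038,62.4229,,
PTP,4267,15583,218.2697,10307,111.5984,,
TMP,6278,24110,279.5762,14063,156.9178,,
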