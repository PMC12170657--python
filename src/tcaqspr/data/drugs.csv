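name,abbreviation,formula,smiles,BP,E,FP,MR,P,MV
Alprazolam,ALP,C17H13ClN4,CC1=NN=C2CN=C(c3ccccc3)c3cc(Cl)ccc3N12,509,77.9,261.6,88.2,35,225.6
Amitriptyline,AMT,C20H23N,CN(C)CCC=C1c2ccccc2CCc2ccccc21,398.2,64.9,174,91.5,36.3,257.8
Amoxapine,AMX,C17H16ClN3O,Clc1ccc2Oc3ccccc3C(=Nc2c1)N1CCNCC1,469.9,73.2,238,86.8,34.4,228.2
Buspirone,BSP,C21H31N5O2,O=C1CC2(CCCC2)CC(=O)N1CCCCN1CCN(c2ncccn2)CC1,613.9,91.1,325.1,106.8,42.4,310.7
Clomipramine,CLM,C19H23ClN2,CN(C)CCCN1c2ccccc2CCc2ccc(Cl)cc21,434.2,69,216.4,93.8,37.2,281.2
Desipramine,DSP,C18H22N2,CNCCCN1c2ccccc2CCc2ccccc21,407.4,65.9,160.5,84.2,33.4,254.3
Desvenlafaxine,DVF,C16H25NO2,CN(C)CC(c1ccc(O)cc1)C1(O)CCCCC1,403.8,69.1,193.2,77.8,30.9,236.1
Diazepam,DZM,C16H13ClN2O,CN1c2ccc(Cl)cc2C(=NCC1=O)c1ccccc1,497.4,76.5,254.6,80.9,32.1,225.9
Fluoxetine,FLX,C17H18F3NO,CNCCC(Oc1ccc(cc1)C(F)(F)F)c1ccccc1,395.1,64.5,192.8,79.9,31.7,266.7
Imipramine,IMP,C19H24N2,CN(C)CCCN1c2ccccc2CCc2ccccc21,403.1,65.4,179.7,88.9,35.3,269.2
Lorazepam,LRZ,C15H10Cl2N2O2,OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O,543.6,86.5,282.6,81,32.1,211.2
Nortriptyline,NTP,C19H21N,CNCCC=C1c2ccccc2CCc2ccccc21,403.4,65.5,194.9,86.8,34.4,242.9
Oxazepam,OZP,C15H11ClN2O2,OC1N=C(c2ccccc2)c2cc(Cl)ccc2NC1=O,516.6,83,266.2,76.4,30.3,201.9
Protriptyline,PTP,C19H21N,CNCCCC1c2ccccc2C=Cc2ccccc21,407.7,66,198.3,84.8,33.6,256.5
Trimipramine,TMP,C20H26N2,CC(CN(C)C)CN1c2ccccc2CCc2ccccc21,411.8,66.4,183.3,93.5,37.1,286.1
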