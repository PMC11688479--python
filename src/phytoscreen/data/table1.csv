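id,name,smiles,V1,V2,V3,cluster,is_representative
c01,cycloartenol,CC(CCC=C(C)C)C1CCC2(C1(CCC34C2CCC5C3(C4)CCC(C5(C)C)O)C)C,35.95328426,5.281447471,-60.05988609,1,FALSE
c02,sitogluside,CCC(CCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)OC5C(C(C(C(O5)CO)O)O)O)C)C)C(C)C,40.93408991,23.39484502,-69.09622853,1,TRUE
c03,isorhamnetin,COC1=C(C=CC(=C1)C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O,-45.14556035,122.8726886,-20.70020026,2,FALSE
c04,kaempferol,C1=CC(=CC=C1C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O,-36.61972104,121.4483762,-35.90034263,2,TRUE
c05,anonaine,C1CNC2CC3=CC=CC=C3C4=C2C1=CC5=C4OCO5,10.27514164,-104.4951622,80.00591538,3,FALSE
c06,remerin,CN1CCC2=CC3=C(C4=C2C1CC5=CC=CC=C54)OCO3,-0.424218041,-94.74319612,87.46698128,3,FALSE
c07,quercetin,C1=CC(=C(C=C1C2=C(C(=O)C3=C(C=C(C=C3O2)O)O)O)O)O,-29.00356636,119.5613867,-21.19470978,2,FALSE
c08,machiline,COC1=C(C=C2C(NCCC2=C1)CC3=CC=C(C=C3)O)O,13.30287557,-51.76793009,21.76064704,3,FALSE
c09,o-nornuciferine,CN1CCC2=CC(=C(C3=C2C1CC4=CC=CC=C43)OC)O,-1.523418171,-84.98220215,62.35640523,3,FALSE
c10,leucodelphinidin,C1=C(C=C(C(=C1O)O)O)C2C(C(C3=C(C=C(C=C3O2)O)O)O)O,-46.1954924,55.16171064,-40.39702155,2,FALSE
c11,sitosterol,CCC(CCC(C)C1CCC2C1(CCC3C2CC=C4C3(CCC(C4)O)C)C)C(C)C,40.24398367,15.71520654,-52.05702476,1,FALSE
c12,ent-epicatechin,C1C(C(OC2=CC(=CC(=C21)O)O)C3=CC(=C(C=C3)O)O)O,-33.19215336,56.1836017,-29.13674847,2,FALSE
c13,leucocyanidin,C1=CC(=C(C=C1C2C(C(C3=C(C=C(C=C3O2)O)O)O)O)O)O,-49.74114868,54.14480073,-24.83973799,2,FALSE
c14,nuciferine,CN1CCC2=CC(=C(C3=C2C1CC4=CC=CC=C43)OC)OC,9.217775785,-74.85162786,73.25581385,3,TRUE
c15,armepavine,CN1CCC2=CC(=C(C=C2C1CC3=CC=C(C=C3)O)OC)OC,7.111890518,-44.31980445,31.53113958,3,FALSE
c16,dehydronuciferine,CN1CCC2=CC(=C(C3=C2C1=CC4=CC=CC=C43)OC)OC,12.37675032,-32.78793245,9.977769123,3,FALSE
c17,n-nornuciferine,COC1=C(C2=C3C(CC4=CC=CC=C42)NCCC3=C1)OC,17.25403315,-86.55540912,62.78189844,3,FALSE
c18,5-o-methyladenosine,COCC1C(C(C(O1)N2C=NC3=C(N=CN=C32)N)O)O,55.17545358,0.739200882,-75.75466988,1,FALSE
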