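dilution,ratio,bme,bmf,chla,mg,cn,rfu
1,1,960.0,770.0,7515.6,204.5,108222.7,1689562
2,0.5,436.7,420.0,4163.1,109.6,61578.1,1200521
5,0.2,150.0,177.5,1567.0,27.6,34113.3,853994
10,0.1,66.7,79.3,892.4,10.6,13136.7,610195
20,0.05,35.8,31.4,382.1,28.4,10664.1,369087
50,0.02,14.2,15.0,182.3,13.8,3757.8,189411
100,0.01,10.0,9.3,90.9,15.4,1699.2,112247
200,0.005,<LOD,2.5,54.6,17.5,472.7,63474
500,0.002,<LOD,1.4,20.1,11.0,371.1,32556
1000,0.001,<LOD,<LOD,12.3,6.9,105.5,26938
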