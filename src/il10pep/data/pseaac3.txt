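# Physicochemical amino-acid distance: root mean squared difference of
# standardized hydrophobicity, hydrophilicity (Hopp & Woods 1981) and
# side-chain mass -- the sequence-correlation construction of Chou's
# pseudo-amino-acid composition (Chou K.C. (2001) Proteins 43:246-255).
          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
A    0.0000   0.6619   1.6377   1.7450   1.6171   0.3202   1.4193   1.0054   1.9933   0.9360   1.1762   1.1890   0.6158   1.4137   2.7130   0.6159   0.6994   0.6760   2.3807   1.8606
C    0.6619   0.0000   1.4369   1.4613   1.0994   0.9406   0.8005   0.7172   1.6993   0.5527   0.5827   0.7633   0.3376   0.9067   2.3190   0.5758   0.2759   0.4986   1.7808   1.2178
D    1.6377   1.4369   0.0000   0.2846   2.1848   1.6603   1.2007   2.0018   0.4454   1.8791   1.6361   0.8646   1.1504   0.8973   1.2573   1.0771   1.1916   1.8404   2.5992   1.9945
E    1.7450   1.4613   0.2846   0.0000   2.0713   1.8108   1.1090   1.9629   0.4503   1.8473   1.5557   0.9085   1.2102   0.8642   1.1886   1.2034   1.2448   1.8467   2.4320   1.8533
F    1.6171   1.0994   2.1848   2.0713   0.0000   1.9351   1.1384   0.6955   2.3500   0.6907   0.5801   1.5661   1.3696   1.5112   2.7853   1.6504   1.3171   0.9723   0.8284   0.6336
G    0.3202   0.9406   1.6603   1.8108   1.9351   0.0000   1.6450   1.3203   2.0329   1.2558   1.4768   1.3247   0.8143   1.5738   2.7761   0.7015   0.9083   0.9937   2.6920   2.1555
H    1.4193   0.8005   1.2007   1.1090   1.1384   1.6450   0.0000   1.2255   1.2705   1.0667   0.6770   0.5556   0.8405   0.3927   1.6985   1.0165   0.7396   1.1926   1.4685   0.8302
I    1.0054   0.7172   2.0018   1.9629   0.6955   1.3203   1.2255   0.0000   2.2774   0.1896   0.5787   1.4201   0.9730   1.4856   2.8738   1.2329   0.9779   0.3349   1.5213   1.1758
K    1.9933   1.6993   0.4454   0.4503   2.3500   2.0329   1.2705   2.2774   0.0000   2.1391   1.8329   1.0034   1.4582   0.9438   0.8127   1.3964   1.4562   2.1411   2.6352   2.0423
L    0.9360   0.5527   1.8791   1.8473   0.6907   1.2558   1.0667   0.1896   2.1391   0.0000   0.4524   1.2520   0.8364   1.3198   2.7233   1.0980   0.8191   0.2840   1.4907   1.0802
M    1.1762   0.5827   1.6361   1.5557   0.5801   1.4768   0.6770   0.5787   1.8329   0.4524   0.0000   1.0134   0.8093   0.9978   2.3508   1.0907   0.7579   0.6693   1.2406   0.7222
N    1.1890   0.7633   0.8646   0.9085   1.5661   1.3247   0.5556   1.4201   1.0034   1.2520   1.0134   0.0000   0.6182   0.2715   1.5800   0.6286   0.5322   1.2533   2.0047   1.3614
P    0.6158   0.3376   1.1504   1.2102   1.3696   0.8143   0.8405   0.9730   1.4582   0.8364   0.8093   0.6182   0.0000   0.8153   2.1438   0.2908   0.1691   0.7327   2.0265   1.4353
Q    1.4137   0.9067   0.8973   0.8642   1.5112   1.5738   0.3927   1.4856   0.9438   1.3198   0.9978   0.2715   0.8153   0.0000   1.4290   0.8810   0.7257   1.3748   1.8521   1.2142
R    2.7130   2.3190   1.2573   1.1886   2.7853   2.7761   1.6985   2.8738   0.8127   2.7233   2.3508   1.5800   2.1438   1.4290   0.0000   2.1045   2.0989   2.7799   2.8465   2.3248
S    0.6159   0.5758   1.0771   1.2034   1.6504   0.7015   1.0165   1.2329   1.3964   1.0980   1.0907   0.6286   0.2908   0.8810   2.1045   0.0000   0.3526   0.9576   2.2893   1.6823
T    0.6994   0.2759   1.1916   1.2448   1.3171   0.9083   0.7396   0.9779   1.4562   0.8191   0.7579   0.5322   0.1691   0.7257   2.0989   0.3526   0.0000   0.7512   1.9407   1.3371
V    0.6760   0.4986   1.8404   1.8467   0.9723   0.9937   1.1926   0.3349   2.1411   0.2840   0.6693   1.2533   0.7327   1.3748   2.7799   0.9576   0.7512   0.0000   1.7743   1.3422
W    2.3807   1.7808   2.5992   2.4320   0.8284   2.6920   1.4685   1.5213   2.6352   1.4907   1.2406   2.0047   2.0265   1.8521   2.8465   2.2893   1.9407   1.7743   0.0000   0.6443
Y    1.8606   1.2178   1.9945   1.8533   0.6336   2.1555   0.8302   1.1758   2.0423   1.0802   0.7222   1.3614   1.4353   1.2142   2.3248   1.6823   1.3371   1.3422   0.6443   0.0000
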