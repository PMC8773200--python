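# Grantham amino-acid difference matrix.
# Computed from the composition/polarity/volume formula of
# Grantham R. (1974) Science 185:862-864 (alpha=1.833, beta=0.1018,
# gamma=0.000399), scaled so the mean off-diagonal distance is 100.
# Reproduces the published integer table to ~+/-1.
          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
A    0.0000 195.2609 125.9144 106.8533 112.7299  60.0745  85.6065  93.7859 105.7101  96.3139  84.5509 110.5636  26.9098  90.8809 111.4113  99.2632  58.0998  64.5152 147.9214 111.7354
C  195.2609   0.0000 153.7769 169.6609 204.6580 158.4404 174.0719 197.5099 201.8451 197.6893 195.8122 138.9494 168.8129 154.4342 179.7716 111.8198 149.1258 191.4847 214.6450 193.9802
D  125.9144 153.7769   0.0000  44.6635 176.7590  93.8912  81.3451 168.3026 101.5907 171.9837 160.2377  23.0357 108.0520  61.3653  95.9399  65.5571  85.1883 152.2138 190.8036 160.1483
E  106.8533 169.6609  44.6635   0.0000 140.3970  97.9809  40.8479 134.3391  56.9429 138.5255 126.2512  40.9128  93.8545  29.3123  54.0901  79.8928  65.5877 121.4885 152.4602 122.9388
F  112.7299 204.6580 176.7590 140.3970   0.0000 153.3274 100.1269  21.3051 102.2760  21.8527  28.5655 158.3207 113.8771 115.7394  97.1607 155.0120 102.9944  50.0010  39.7074  21.6382
G   60.0745 158.4404  93.8912  97.9809 153.3274   0.0000  97.6620 135.5974 126.6247 137.8732 127.1123  79.4505  41.6840  87.2813 125.2942  55.3402  59.2345 108.9308 184.0326 147.1200
H   85.6065 174.0719  81.3451  40.8479 100.1269  97.6620   0.0000  94.4619  32.4456  98.8232  86.4578  68.4450  76.3777  24.1157  28.8572  89.0528  46.8145  84.0036 114.7122  83.4383
I   93.7859 197.5099 168.3026 134.3391  21.3051 135.5974  94.4619   0.0000 101.7463   4.8615  10.1343 149.1105  95.5019 108.7094  97.7152 141.9849  89.4006  29.6481  60.6077  33.0913
K  105.7101 201.8451 101.5907  56.9429 102.2760 126.6247  32.4456 101.7463   0.0000 106.4757  94.6147  94.0065 102.8494  53.2985  26.0382 120.6915  77.8436  97.1253 109.5788  84.8982
L   96.3139 197.6893 171.9837 138.5255  21.8527 137.8732  98.8232   4.8615 106.4757   0.0000  14.3220 152.5318  97.9051 112.5897 102.0146 144.2692  92.4761  31.8267  61.0609  35.7244
M   84.5509 195.8122 160.2377 126.2512  28.5655 127.1123  86.4578  10.1343  94.6147  14.3220   0.0000 141.3388  86.7090 101.0322  91.7591 135.0417  81.1466  21.5502  66.7247  35.2691
N  110.5636 138.9494  23.0357  40.9128 158.3207  79.4505  68.4450 149.1105  94.0065 152.5318 141.3388   0.0000  90.2763  45.8125  85.2262  46.3007  64.8597 133.0529 174.0109 142.4169
P   26.9098 168.8129 108.0520  93.8545 113.8771  41.6840  76.3777  95.5019 102.8494  97.9051  86.7090  90.2763   0.0000  75.2350 102.8503  73.4493  37.6132  67.8760 146.8142 109.7601
Q   90.8809 154.4342  61.3653  29.3123 115.7394  87.2813  24.1157 108.7094  53.2985 112.5897 101.0322  45.8125  75.2350   0.0000  42.8704  68.2878  41.1590  96.4527 130.3761  98.9135
R  111.4113 179.7716  95.9399  54.0901  97.1607 125.2942  28.8572  97.7152  26.0382 102.0146  91.7591  85.2262 102.8503  42.8704   0.0000 109.3572  71.0646  95.9234 101.4240  77.2093
S   99.2632 111.8198  65.5571  79.8928 155.0120  55.3402  89.0528 141.9849 120.6915 144.2692 135.0417  46.3007  73.4493  68.2878 109.3572   0.0000  57.8252 123.1962 176.8104 143.2961
T   58.0998 149.1258  85.1883  65.5877 102.9944  59.2345  46.8145  89.4006  77.8436  92.4761  81.1466  64.8597  37.6132  41.1590  71.0646  57.8252   0.0000  69.5879 128.4851  92.3693
V   64.5152 191.4847 152.2138 121.4885  50.0010 108.9308  84.0036  29.6481  97.1253  31.8267  21.5502 133.0529  67.8760  96.4527  95.9234 123.1962  69.5879   0.0000  88.0796  54.7349
W  147.9214 214.6450 190.8036 152.4602  39.7074 184.0326 114.7122  60.6077 109.5788  61.0609  66.7247 174.0109 146.8142 130.3761 101.4240 176.8104 128.4851  88.0796   0.0000  37.1627
Y  111.7354 193.9802 160.1483 122.9388  21.6382 147.1200  83.4383  33.0913  84.8982  35.7244  35.2691 142.4169 109.7601  98.9135  77.2093 143.2961  92.3693  54.7349  37.1627   0.0000
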