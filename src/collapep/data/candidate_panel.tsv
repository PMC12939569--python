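sequence	lr	svm	mlp	cdocker_energy	cdocker_interaction
QICVCDS	high	high	high	125.954	118.496
DVWK	high	low_non	low_non	117.488	106.022
IIEY	high	high	high	105.96	105.308
APMDVG	high	low_non	low_non	100.198	104.216
VIEY	high	high	high	107.679	101.273
CR	high	high	high	51.7598	98.9681
DCPN	high	high	high	84.6444	95.1822
AVIL	low_non	high	low_non	97.2242	91.1243
NWY	high	high	high	94.1639	90.5661
CIMD	high	high	high	87.2086	87.2189
CDF	high	high	high	89.6301	85.0382
VWF	high	high	high	84.9517	82.9004
DPG	high	low_non	low_non	82.186	80.9088
CNL	high	high	high	88.73	80.173
IPT	high	high	high	60.7788	78.4556
CVY	high	high	high	83.7145	77.1025
ANH	low_non	high	high	90.0769	76.6198
WY	high	high	high	74.7127	75.5368
CIH	high	high	high	76.0867	74.1174
APL	low_non	high	high	62.8983	72.4292
APD	high	low_non	high	51.6015	72.3056
PPF	low_non	high	high	47.0456	71.9965
VL	high	high	high	70.8135	66.6751
VY	high	high	high	71.7841	66.6652
CH	high	high	high	70.8717	66.3302
CS	high	low_non	high	65.5785	60.116
MP	high	high	high	38.9863	55.042
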