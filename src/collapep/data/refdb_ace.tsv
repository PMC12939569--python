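sequence	activity	ic50_um	source
PR	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AY	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AF	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AP	ACE inhibitor		database snapshot (alpha1 release)
VG	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AG	ACE inhibitor		database snapshot (alpha1/alpha2 release)
MG	ACE inhibitor		database snapshot (alpha1 release)
WG	ACE inhibitor		database snapshot (alpha1 release)
QG	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AI	ACE inhibitor		database snapshot (alpha1 release)
EG	ACE inhibitor		database snapshot (alpha1/alpha2 release)
NG	ACE inhibitor		database snapshot (alpha1/alpha2 release)
PG	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AR	ACE inhibitor		database snapshot (alpha1/alpha2 release)
PT	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AH	ACE inhibitor		database snapshot (alpha1/alpha2 release)
EK	ACE inhibitor		database snapshot (alpha1/alpha2 release)
DF	ACE inhibitor		database snapshot (alpha1 release)
WL	ACE inhibitor		database snapshot (alpha1 release)
PPL	ACE inhibitor		database snapshot (alpha1 release)
ER	ACE inhibitor		database snapshot (alpha1/alpha2 release)
DR	ACE inhibitor		database snapshot (alpha1/alpha2 release)
AK	ACE inhibitor		database snapshot (alpha1/alpha2 release)
WY	ACE inhibitor		database snapshot (alpha1 release)
IR	ACE inhibitor		database snapshot (alpha2 release)
MF	ACE inhibitor		database snapshot (alpha2 release)
VY	ACE inhibitor	5.2	literature (sardine muscle dipeptide)
PL	ACE inhibitor		database snapshot (alpha2 release)
VK	ACE inhibitor		database snapshot (alpha2 release)
IG	ACE inhibitor		database snapshot (alpha2 release)
VR	ACE inhibitor		database snapshot (alpha2 release)
QK	ACE inhibitor		database snapshot (alpha2 release)
DG	ACE inhibitor		database snapshot (alpha2 release)
NF	ACE inhibitor		database snapshot (alpha2 release)
NK	ACE inhibitor		database snapshot (alpha2 release)
EY	ACE inhibitor		database snapshot (alpha2 release)
PH	ACE inhibitor		database snapshot (alpha2 release)
DY	ACE inhibitor		database snapshot (alpha2 release)
DM	ACE inhibitor		database snapshot (alpha2 release)
IL	ACE inhibitor		database snapshot (alpha2 release)
EF	ACE inhibitor		database snapshot (alpha2 release)
DL	ACE inhibitor		database snapshot (alpha2 release; listed twice in source, deduplicated)
PPG	ACE inhibitor		literature (collagen tripeptide, 23.14% inhibition at 1000 uL/mL)
APG	ACE inhibitor		literature (collagen tripeptide)
PK	ACE inhibitor	4092	literature (dipeptide)
CDF	ACE inhibitor	192.17	literature (tripeptide)
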