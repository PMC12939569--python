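method	rank	gene
MCC	1	CASP8
MCC	2	HSP90AA1
MCC	3	BCL2
MCC	4	MAPK1
MCC	5	XIAP
MCC	6	CASP3
MCC	7	CASP7
MCC	8	STAT3
MCC	9	SRC
MCC	10	BIRC2
MNC	1	CASP8
MNC	2	HSP90AA1
MNC	3	BCL2
MNC	4	MAPK1
MNC	5	XIAP
MNC	6	CASP3
MNC	7	CASP7
MNC	8	STAT3
MNC	9	SRC
MNC	10	BIRC2
Degree	1	SRC
Degree	2	STAT3
Degree	3	SIRT1
Degree	4	ABL1
Degree	5	MMP9
Degree	6	CASP3
Degree	7	DLG4
Degree	8	BCL2
Degree	9	HSP90AA1
Degree	10	CASP8
Stress	1	SRC
Stress	2	STAT3
Stress	3	IDE
Stress	4	ADRB1
Stress	5	DLG4
Stress	6	CASP3
Stress	7	NPPA
Stress	8	HSP90AA1
Stress	9	BCL2
Stress	10	APP
Radiality	1	SRC
Radiality	2	STAT3
Radiality	3	FYN
Radiality	4	ADRB2
Radiality	5	ADRB1
Radiality	6	CASP3
Radiality	7	DLG4
Radiality	8	MAPK1
Radiality	9	BCL2
Radiality	10	HSP90AA1
Betweenness	1	SRC
Betweenness	2	STAT3
Betweenness	3	IDE
Betweenness	4	ABL1
Betweenness	5	ADRB1
Betweenness	6	DLG4
Betweenness	7	NPPA
Betweenness	8	BCL2
Betweenness	9	HSP90AA1
Betweenness	10	APP
Closeness	1	SRC
Closeness	2	STAT3
Closeness	3	FYN
Closeness	4	SYK
Closeness	5	ABL1
Closeness	6	CASP3
Closeness	7	DLG4
Closeness	8	MAPK1
Closeness	9	BCL2
Closeness	10	HSP90AA1
EPC	1	SRC
EPC	2	STAT3
EPC	3	FYN
EPC	4	SYK
EPC	5	PIK3CA
EPC	6	CASP3
EPC	7	MAPK1
EPC	8	HSP90AA1
EPC	9	BCL2
EPC	10	CASP8
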