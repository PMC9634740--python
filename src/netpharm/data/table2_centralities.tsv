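name	Betweenness	Closeness	Degree	Eigenvector	LAC	Network
RELA	1.507142857	0.769230769	7	0.25598225	4.571428571	5.333333333
MYC	2.078571429	0.909090909	9	0.326317787	6.444444444	8.172619048
MAPK8	0.821428571	0.769230769	7	0.263347566	5.142857143	6
FOS	2.078571429	0.909090909	9	0.326427132	6.444444444	8.172619048
TP53	2.192857143	0.909090909	9	0.326792687	6.444444444	8.130952381
JUN	3.164285714	1	10	0.354707539	7	10
MAPK14	1.942857143	0.833333333	8	0.295108497	5.5	6.595238095
CCND1	1.257142857	0.769230769	7	0.263187557	4.857142857	5.666666667
ESR1	2.192857143	0.909090909	9	0.326792687	6.444444444	8.130952381
MAPK1	1.942857143	0.833333333	8	0.295108497	5.5	6.595238095
AKT1	0.821428571	0.769230769	7	0.26312241	5.142857143	6
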