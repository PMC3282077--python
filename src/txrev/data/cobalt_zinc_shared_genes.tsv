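gene	direction	fc_C0	fc_ZCC
P4HA1	up	3.12	-1.32
ADM	up	6.67	-4.43
ANGPTL4	up	2.83	-1.99
BNIP3L	up	4.51	-2.09
NDRG1	up	9.40	-5.30
SLC2A1	up	1.99	-1.12
AK3L1	up	1.75	-1.29
BHLHE40	up	4.63	-2.26
C7orf68	up	3.00	-2.25
CCNG2	up	2.01	-2.30
ENO2	up	3.90	-2.34
KDM3A	up	3.98	-1.88
P4HA2	up	1.82	-1.55
PGK1	up	1.54	-1.13
CA9	up	7.60	-1.35
EGLN1	up	2.90	-1.75
FAM162A	up	2.35	-1.56
GBE1	up	3.17	-1.84
HK2	up	1.85	-1.17
PFKFB4	up	16.27	-4.59
ALDOA	up	1.74	-1.32
ALDOC	up	6.93	-3.57
ANG	up	1.61	-1.79
ANKRD37	up	5.43	-3.73
HMOX1	up	6.47	-2.87
INSIG2	up	2.57	-2.11
MAFF	up	1.87	-1.48
PDK1	up	2.56	-1.18
PFKFB3	up	1.55	-1.41
PGM1	up	1.97	-1.41
SPAG4	up	2.88	-1.19
TMEM45A	up	5.45	-2.53
ZNF292	up	2.69	-1.56
ABCB6	up	2.73	-1.90
ANKZF1	up	2.74	-1.75
CITED2	up	1.71	-1.87
CSRP2	up	2.10	-2.05
FOS	up	2.99	-1.83
GYS1	up	1.62	-1.27
HCFC1R1	up	1.69	-1.87
KDM4B	up	2.21	-1.82
LIMCH1	up	1.99	-1.46
RAB20	up	3.88	-2.20
RBPJ	up	1.58	-1.36
RIOK3	up	1.61	-1.32
RORA	up	3.98	-2.79
SAP30	up	1.77	-1.72
SCD	up	1.72	-1.67
SERTAD2	up	1.66	-1.57
SLC16A3	up	1.57	-1.27
STBD1	up	1.58	-1.75
WSB1	up	1.79	-1.29
YEATS2	up	1.58	-1.26
SPOCK1	up	1.57	-1.37
EEF1E1	down	-1.68	-1.01
BOP1	down	-1.68	1.46
DDX21	down	-1.61	1.56
IL18R1	down	-1.95	1.97
NIP7	down	-1.58	1.24
RANGAP1	down	-1.55	1.29
RRP15	down	-1.65	1.36
RRS1	down	-1.59	1.56
RUVBL1	down	-1.80	1.53
SLC25A15	down	-1.75	1.33
SRM	down	-1.55	1.48
WDR4	down	-1.51	1.65
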