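# Additive hydrophobic contact potential: e_ij = -(h'_i + h'_j)/2,
# h' a shifted Kyte-Doolittle hydropathy (all entries attractive).
 	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-3.400	-3.575	-2.075	-2.075	-3.650	-2.850	-2.150	-4.075	-1.975	-3.900	-3.425	-2.075	-2.550	-2.075	-1.825	-2.750	-2.775	-4.000	-2.725	-2.625
C	-3.575	-3.750	-2.250	-2.250	-3.825	-3.025	-2.325	-4.250	-2.150	-4.075	-3.600	-2.250	-2.725	-2.250	-2.000	-2.925	-2.950	-4.175	-2.900	-2.800
D	-2.075	-2.250	-0.750	-0.750	-2.325	-1.525	-0.825	-2.750	-0.650	-2.575	-2.100	-0.750	-1.225	-0.750	-0.500	-1.425	-1.450	-2.675	-1.400	-1.300
E	-2.075	-2.250	-0.750	-0.750	-2.325	-1.525	-0.825	-2.750	-0.650	-2.575	-2.100	-0.750	-1.225	-0.750	-0.500	-1.425	-1.450	-2.675	-1.400	-1.300
F	-3.650	-3.825	-2.325	-2.325	-3.900	-3.100	-2.400	-4.325	-2.225	-4.150	-3.675	-2.325	-2.800	-2.325	-2.075	-3.000	-3.025	-4.250	-2.975	-2.875
G	-2.850	-3.025	-1.525	-1.525	-3.100	-2.300	-1.600	-3.525	-1.425	-3.350	-2.875	-1.525	-2.000	-1.525	-1.275	-2.200	-2.225	-3.450	-2.175	-2.075
H	-2.150	-2.325	-0.825	-0.825	-2.400	-1.600	-0.900	-2.825	-0.725	-2.650	-2.175	-0.825	-1.300	-0.825	-0.575	-1.500	-1.525	-2.750	-1.475	-1.375
I	-4.075	-4.250	-2.750	-2.750	-4.325	-3.525	-2.825	-4.750	-2.650	-4.575	-4.100	-2.750	-3.225	-2.750	-2.500	-3.425	-3.450	-4.675	-3.400	-3.300
K	-1.975	-2.150	-0.650	-0.650	-2.225	-1.425	-0.725	-2.650	-0.550	-2.475	-2.000	-0.650	-1.125	-0.650	-0.400	-1.325	-1.350	-2.575	-1.300	-1.200
L	-3.900	-4.075	-2.575	-2.575	-4.150	-3.350	-2.650	-4.575	-2.475	-4.400	-3.925	-2.575	-3.050	-2.575	-2.325	-3.250	-3.275	-4.500	-3.225	-3.125
M	-3.425	-3.600	-2.100	-2.100	-3.675	-2.875	-2.175	-4.100	-2.000	-3.925	-3.450	-2.100	-2.575	-2.100	-1.850	-2.775	-2.800	-4.025	-2.750	-2.650
N	-2.075	-2.250	-0.750	-0.750	-2.325	-1.525	-0.825	-2.750	-0.650	-2.575	-2.100	-0.750	-1.225	-0.750	-0.500	-1.425	-1.450	-2.675	-1.400	-1.300
P	-2.550	-2.725	-1.225	-1.225	-2.800	-2.000	-1.300	-3.225	-1.125	-3.050	-2.575	-1.225	-1.700	-1.225	-0.975	-1.900	-1.925	-3.150	-1.875	-1.775
Q	-2.075	-2.250	-0.750	-0.750	-2.325	-1.525	-0.825	-2.750	-0.650	-2.575	-2.100	-0.750	-1.225	-0.750	-0.500	-1.425	-1.450	-2.675	-1.400	-1.300
R	-1.825	-2.000	-0.500	-0.500	-2.075	-1.275	-0.575	-2.500	-0.400	-2.325	-1.850	-0.500	-0.975	-0.500	-0.250	-1.175	-1.200	-2.425	-1.150	-1.050
S	-2.750	-2.925	-1.425	-1.425	-3.000	-2.200	-1.500	-3.425	-1.325	-3.250	-2.775	-1.425	-1.900	-1.425	-1.175	-2.100	-2.125	-3.350	-2.075	-1.975
T	-2.775	-2.950	-1.450	-1.450	-3.025	-2.225	-1.525	-3.450	-1.350	-3.275	-2.800	-1.450	-1.925	-1.450	-1.200	-2.125	-2.150	-3.375	-2.100	-2.000
V	-4.000	-4.175	-2.675	-2.675	-4.250	-3.450	-2.750	-4.675	-2.575	-4.500	-4.025	-2.675	-3.150	-2.675	-2.425	-3.350	-3.375	-4.600	-3.325	-3.225
W	-2.725	-2.900	-1.400	-1.400	-2.975	-2.175	-1.475	-3.400	-1.300	-3.225	-2.750	-1.400	-1.875	-1.400	-1.150	-2.075	-2.100	-3.325	-2.050	-1.950
Y	-2.625	-2.800	-1.300	-1.300	-2.875	-2.075	-1.375	-3.300	-1.200	-3.125	-2.650	-1.300	-1.775	-1.300	-1.050	-1.975	-2.000	-3.225	-1.950	-1.850
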