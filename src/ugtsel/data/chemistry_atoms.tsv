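residue	atom	element	partial_charge	electronegativity	hb_acceptor_lone_pairs	is_hb_donor_h
A	CA	C	0.100270	2.55	0	0
A	C1	C	-0.039123	2.55	0	0
A	H1	H	0.025218	2.20	0	0
A	H2	H	0.025218	2.20	0	0
A	H3	H	0.025218	2.20	0	0
C	CA	C	0.112000	2.55	0	0
C	C1	C	0.016263	2.55	0	0
C	S1	S	-0.177119	2.58	0	0
C	H1	H	0.039984	2.20	0	0
C	H2	H	0.039984	2.20	0	0
C	H3	H	0.102286	2.20	0	1
D	CA	C	0.108368	2.55	0	0
D	C1	C	0.012926	2.55	0	0
D	C2	C	0.043528	2.55	0	0
D	H1	H	0.035069	2.20	0	0
D	H2	H	0.035069	2.20	0	0
D	O1	O	-0.550091	3.44	2	0
D	O2	O	-0.550091	3.44	2	0
E	CA	C	0.103483	2.55	0	0
E	C1	C	-0.021914	2.55	0	0
E	C2	C	-0.011085	2.55	0	0
E	H1	H	0.029227	2.20	0	0
E	H2	H	0.029227	2.20	0	0
E	C3	C	0.041459	2.55	0	0
E	H3	H	0.032923	2.20	0	0
E	H4	H	0.032923	2.20	0	0
E	O1	O	-0.550171	3.44	2	0
E	O2	O	-0.550171	3.44	2	0
F	CA	C	0.107188	2.55	0	0
F	C1	C	-0.001790	2.55	0	0
F	C2	C	-0.045879	2.55	0	0
F	H1	H	0.033806	2.20	0	0
F	H2	H	0.033806	2.20	0	0
F	C3	C	-0.058969	2.55	0	0
F	C4	C	-0.058969	2.55	0	0
F	C5	C	-0.061993	2.55	0	0
F	H3	H	0.062562	2.20	0	0
F	C6	C	-0.061993	2.55	0	0
F	H4	H	0.062562	2.20	0	0
F	C7	C	-0.062249	2.55	0	0
F	H5	H	0.062279	2.20	0	0
F	H6	H	0.062279	2.20	0	0
F	H7	H	0.062269	2.20	0	0
G	CA	C	0.091814	2.55	0	0
G	H1	H	0.054743	2.20	0	0
H	CA	C	0.108760	2.55	0	0
H	C1	C	0.017179	2.55	0	0
H	C2	C	0.060240	2.55	0	0
H	H1	H	0.035492	2.20	0	0
H	H2	H	0.035492	2.20	0	0
H	C3	C	0.023612	2.55	0	0
H	N1	N	-0.241949	3.04	1	0
H	N2	N	-0.350904	3.04	0	0
H	H3	H	0.083556	2.20	0	0
H	C4	C	0.092257	2.55	0	0
H	H4	H	0.166907	2.20	0	1
H	H5	H	0.104088	2.20	0	0
I	CA	C	0.105692	2.55	0	0
I	C1	C	-0.018481	2.55	0	0
I	C2	C	-0.060456	2.55	0	0
I	C3	C	-0.051516	2.55	0	0
I	H1	H	0.032171	2.20	0	0
I	H2	H	0.023392	2.20	0	0
I	H3	H	0.023392	2.20	0	0
I	H4	H	0.023392	2.20	0	0
I	C4	C	-0.065054	2.55	0	0
I	H5	H	0.026718	2.20	0	0
I	H6	H	0.026718	2.20	0	0
I	H7	H	0.023046	2.20	0	0
I	H8	H	0.023046	2.20	0	0
I	H9	H	0.023046	2.20	0	0
K	CA	C	0.103126	2.55	0	0
K	C1	C	-0.026933	2.55	0	0
K	C2	C	-0.045904	2.55	0	0
K	H1	H	0.028848	2.20	0	0
K	H2	H	0.028848	2.20	0	0
K	C3	C	-0.003595	2.55	0	0
K	H3	H	0.026945	2.20	0	0
K	H4	H	0.026945	2.20	0	0
K	C4	C	0.073932	2.55	0	0
K	H5	H	0.032441	2.20	0	0
K	H6	H	0.032441	2.20	0	0
K	N1	N	-0.357561	3.04	0	0
K	H7	H	0.092194	2.20	0	0
K	H8	H	0.092194	2.20	0	0
K	H9	H	0.344007	2.20	0	1
K	H10	H	0.344007	2.20	0	1
K	H11	H	0.344007	2.20	0	1
L	CA	C	0.103367	2.55	0	0
L	C1	C	-0.024826	2.55	0	0
L	C2	C	-0.045080	2.55	0	0
L	H1	H	0.029109	2.20	0	0
L	H2	H	0.029109	2.20	0	0
L	C3	C	-0.062700	2.55	0	0
L	C4	C	-0.062700	2.55	0	0
L	H3	H	0.029776	2.20	0	0
L	H4	H	0.023309	2.20	0	0
L	H5	H	0.023309	2.20	0	0
L	H6	H	0.023309	2.20	0	0
L	H7	H	0.023309	2.20	0	0
L	H8	H	0.023309	2.20	0	0
L	H9	H	0.023309	2.20	0	0
M	CA	C	0.103911	2.55	0	0
M	C1	C	-0.018029	2.55	0	0
M	C2	C	-0.004977	2.55	0	0
M	H1	H	0.029692	2.20	0	0
M	H2	H	0.029692	2.20	0	0
M	S1	S	-0.165357	2.58	2	0
M	H3	H	0.038088	2.20	0	0
M	H4	H	0.038088	2.20	0	0
M	C3	C	-0.018399	2.55	0	0
M	H5	H	0.034380	2.20	0	0
M	H6	H	0.034380	2.20	0	0
M	H7	H	0.034380	2.20	0	0
N	CA	C	0.111937	2.55	0	0
N	C1	C	0.052212	2.55	0	0
N	C2	C	0.219087	2.55	0	0
N	H1	H	0.038912	2.20	0	0
N	H2	H	0.038912	2.20	0	0
N	N1	N	-0.369614	3.04	0	0
N	O1	O	-0.275288	3.44	2	0
N	H3	H	0.159101	2.20	0	1
N	H4	H	0.159101	2.20	0	1
P	CA	C	0.105660	2.55	0	0
P	C1	C	-0.025727	2.55	0	0
P	C2	C	-0.038584	2.55	0	0
P	H1	H	0.028900	2.20	0	0
P	H2	H	0.028900	2.20	0	0
P	C3	C	-0.004013	2.55	0	0
P	H3	H	0.028029	2.20	0	0
P	H4	H	0.028029	2.20	0	0
P	N	N	-0.304413	3.04	0	0
P	H5	H	0.042812	2.20	0	0
P	H6	H	0.042812	2.20	0	0
Q	CA	C	0.103618	2.55	0	0
Q	C1	C	-0.018362	2.55	0	0
Q	C2	C	0.028297	2.55	0	0
Q	H1	H	0.029363	2.20	0	0
Q	H2	H	0.029363	2.20	0	0
Q	C3	C	0.216990	2.55	0	0
Q	H3	H	0.036739	2.20	0	0
Q	H4	H	0.036739	2.20	0	0
Q	N1	N	-0.369679	3.04	0	0
Q	O1	O	-0.275373	3.44	2	0
Q	H5	H	0.159100	2.20	0	1
Q	H6	H	0.159100	2.20	0	1
R	CA	C	0.103241	2.55	0	0
R	C1	C	-0.024142	2.55	0	0
R	C2	C	-0.020250	2.55	0	0
R	H1	H	0.028964	2.20	0	0
R	H2	H	0.028964	2.20	0	0
R	C3	C	0.063907	2.55	0	0
R	H3	H	0.029973	2.20	0	0
R	H4	H	0.029973	2.20	0	0
R	N1	N	-0.278364	3.04	0	0
R	H5	H	0.066415	2.20	0	0
R	H6	H	0.066415	2.20	0	0
R	C4	C	0.338266	2.55	0	0
R	H7	H	0.259568	2.20	0	1
R	N2	N	-0.291038	3.04	0	0
R	N3	N	-0.291038	3.04	0	0
R	H8	H	0.256270	2.20	0	1
R	H9	H	0.256270	2.20	0	1
R	H10	H	0.256270	2.20	0	1
R	H11	H	0.256270	2.20	0	1
S	CA	C	0.126466	2.55	0	0
S	C1	C	0.069023	2.55	0	0
S	O1	O	-0.394136	3.44	2	0
S	H1	H	0.058645	2.20	0	0
S	H2	H	0.058645	2.20	0	0
S	H3	H	0.210140	2.20	0	1
T	CA	C	0.129045	2.55	0	0
T	C1	C	0.077045	2.55	0	0
T	C2	C	-0.036811	2.55	0	0
T	O1	O	-0.391174	3.44	2	0
T	H1	H	0.062026	2.20	0	0
T	H2	H	0.025747	2.20	0	0
T	H3	H	0.025747	2.20	0	0
T	H4	H	0.025747	2.20	0	0
T	H5	H	0.210535	2.20	0	1
V	CA	C	0.105438	2.55	0	0
V	C1	C	-0.021064	2.55	0	0
V	C2	C	-0.060711	2.55	0	0
V	C3	C	-0.060711	2.55	0	0
V	H1	H	0.031897	2.20	0	0
V	H2	H	0.023382	2.20	0	0
V	H3	H	0.023382	2.20	0	0
V	H4	H	0.023382	2.20	0	0
V	H5	H	0.023382	2.20	0	0
V	H6	H	0.023382	2.20	0	0
V	H7	H	0.023382	2.20	0	0
W	CA	C	0.107267	2.55	0	0
W	C1	C	0.000323	2.55	0	0
W	C2	C	-0.020503	2.55	0	0
W	H1	H	0.033885	2.20	0	0
W	H2	H	0.033885	2.20	0	0
W	C3	C	0.004974	2.55	0	0
W	C4	C	0.002634	2.55	0	0
W	N1	N	-0.360889	3.04	0	0
W	H3	H	0.081873	2.20	0	0
W	C5	C	-0.052563	2.55	0	0
W	C6	C	0.045630	2.55	0	0
W	H4	H	0.165937	2.20	0	1
W	C7	C	-0.061509	2.55	0	0
W	H5	H	0.062991	2.20	0	0
W	C8	C	-0.038003	2.55	0	0
W	C9	C	-0.060159	2.55	0	0
W	H6	H	0.062293	2.20	0	0
W	H7	H	0.064491	2.20	0	0
W	H8	H	0.062346	2.20	0	0
Y	CA	C	0.107188	2.55	0	0
Y	C1	C	-0.001785	2.55	0	0
Y	C2	C	-0.045610	2.55	0	0
Y	H1	H	0.033806	2.20	0	0
Y	H2	H	0.033806	2.20	0	0
Y	C3	C	-0.055294	2.55	0	0
Y	C4	C	-0.055294	2.55	0	0
Y	C5	C	-0.019954	2.55	0	0
Y	H3	H	0.062698	2.20	0	0
Y	C6	C	-0.019954	2.55	0	0
Y	H4	H	0.062698	2.20	0	0
Y	C7	C	0.115095	2.55	0	0
Y	H5	H	0.066191	2.20	0	0
Y	H6	H	0.066191	2.20	0	0
Y	O1	O	-0.507967	3.44	2	0
Y	H7	H	0.293092	2.20	0	1
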