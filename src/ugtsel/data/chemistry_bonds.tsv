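residue	atom1	atom2	length
A	CA	C1	1.540
A	C1	H1	1.090
A	C1	H2	1.090
A	C1	H3	1.090
C	CA	C1	1.540
C	C1	S1	1.810
C	C1	H1	1.090
C	C1	H2	1.090
C	S1	H3	1.340
D	CA	C1	1.540
D	C1	C2	1.540
D	C2	O1	1.220
D	C2	O2	1.250
D	C1	H1	1.090
D	C1	H2	1.090
E	CA	C1	1.540
E	C1	C2	1.540
E	C2	C3	1.540
E	C3	O1	1.220
E	C3	O2	1.250
E	C1	H1	1.090
E	C1	H2	1.090
E	C2	H3	1.090
E	C2	H4	1.090
F	CA	C1	1.540
F	C1	C2	1.540
F	C2	C3	1.400
F	C3	C5	1.400
F	C5	C7	1.400
F	C7	C6	1.400
F	C6	C4	1.400
F	C4	C2	1.400
F	C1	H1	1.090
F	C1	H2	1.090
F	C3	H3	1.090
F	C5	H5	1.090
F	C7	H7	1.090
F	C6	H6	1.090
F	C4	H4	1.090
G	CA	H1	1.090
H	CA	C1	1.540
H	C1	C2	1.540
H	C2	C3	1.400
H	C3	N2	1.340
H	N2	C4	1.340
H	C4	N1	1.340
H	N1	C2	1.340
H	C1	H1	1.090
H	C1	H2	1.090
H	C3	H3	1.090
H	N2	H4	1.010
H	C4	H5	1.090
I	CA	C1	1.540
I	C1	C2	1.540
I	C1	C3	1.540
I	C3	C4	1.540
I	C1	H1	1.090
I	C2	H2	1.090
I	C2	H3	1.090
I	C2	H4	1.090
I	C3	H5	1.090
I	C3	H6	1.090
I	C4	H7	1.090
I	C4	H8	1.090
I	C4	H9	1.090
K	CA	C1	1.540
K	C1	C2	1.540
K	C2	C3	1.540
K	C3	C4	1.540
K	C4	N1	1.470
K	C1	H1	1.090
K	C1	H2	1.090
K	C2	H3	1.090
K	C2	H4	1.090
K	C3	H5	1.090
K	C3	H6	1.090
K	C4	H7	1.090
K	C4	H8	1.090
K	N1	H9	1.010
K	N1	H10	1.010
K	N1	H11	1.010
L	CA	C1	1.540
L	C1	C2	1.540
L	C2	C3	1.540
L	C2	C4	1.540
L	C1	H1	1.090
L	C1	H2	1.090
L	C2	H3	1.090
L	C3	H4	1.090
L	C3	H5	1.090
L	C3	H6	1.090
L	C4	H7	1.090
L	C4	H8	1.090
L	C4	H9	1.090
M	CA	C1	1.540
M	C1	C2	1.540
M	C2	S1	1.810
M	S1	C3	1.810
M	C1	H1	1.090
M	C1	H2	1.090
M	C2	H3	1.090
M	C2	H4	1.090
M	C3	H5	1.090
M	C3	H6	1.090
M	C3	H7	1.090
N	CA	C1	1.540
N	C1	C2	1.540
N	C2	N1	1.470
N	C2	O1	1.220
N	C1	H1	1.090
N	C1	H2	1.090
N	N1	H3	1.010
N	N1	H4	1.010
P	CA	C1	1.540
P	C1	C2	1.540
P	C2	C3	1.540
P	C3	N	1.470
P	N	CA	1.470
P	C1	H1	1.090
P	C1	H2	1.090
P	C2	H3	1.090
P	C2	H4	1.090
P	C3	H5	1.090
P	C3	H6	1.090
Q	CA	C1	1.540
Q	C1	C2	1.540
Q	C2	C3	1.540
Q	C3	N1	1.470
Q	C3	O1	1.220
Q	C1	H1	1.090
Q	C1	H2	1.090
Q	C2	H3	1.090
Q	C2	H4	1.090
Q	N1	H5	1.010
Q	N1	H6	1.010
R	CA	C1	1.540
R	C1	C2	1.540
R	C2	C3	1.540
R	C3	N1	1.470
R	N1	C4	1.470
R	C4	N2	1.470
R	C4	N3	1.320
R	C1	H1	1.090
R	C1	H2	1.090
R	C2	H3	1.090
R	C2	H4	1.090
R	C3	H5	1.090
R	C3	H6	1.090
R	N1	H7	1.010
R	N2	H8	1.010
R	N2	H9	1.010
R	N3	H10	1.010
R	N3	H11	1.010
S	CA	C1	1.540
S	C1	O1	1.430
S	C1	H1	1.090
S	C1	H2	1.090
S	O1	H3	0.960
T	CA	C1	1.540
T	C1	C2	1.540
T	C1	O1	1.430
T	C1	H1	1.090
T	C2	H2	1.090
T	C2	H3	1.090
T	C2	H4	1.090
T	O1	H5	0.960
V	CA	C1	1.540
V	C1	C2	1.540
V	C1	C3	1.540
V	C1	H1	1.090
V	C2	H2	1.090
V	C2	H3	1.090
V	C2	H4	1.090
V	C3	H5	1.090
V	C3	H6	1.090
V	C3	H7	1.090
W	CA	C1	1.540
W	C1	C2	1.540
W	C2	C3	1.400
W	C3	N1	1.340
W	N1	C6	1.340
W	C6	C8	1.400
W	C8	C9	1.400
W	C9	C7	1.400
W	C7	C5	1.400
W	C5	C4	1.400
W	C4	C2	1.400
W	C4	C6	1.400
W	C1	H1	1.090
W	C1	H2	1.090
W	C3	H3	1.090
W	N1	H4	1.010
W	C8	H7	1.090
W	C9	H8	1.090
W	C7	H6	1.090
W	C5	H5	1.090
Y	CA	C1	1.540
Y	C1	C2	1.540
Y	C2	C3	1.400
Y	C3	C5	1.400
Y	C5	C7	1.400
Y	C7	O1	1.430
Y	C7	C6	1.400
Y	C6	C4	1.400
Y	C4	C2	1.400
Y	C1	H1	1.090
Y	C1	H2	1.090
Y	C3	H3	1.090
Y	C5	H5	1.090
Y	O1	H7	0.960
Y	C6	H6	1.090
Y	C4	H4	1.090
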