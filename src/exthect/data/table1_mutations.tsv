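protein_id	substitution	residue_number	reported_location
NED4L	Y679C	679	N-lobe
NED4L	Q974H	974	N-lobe
NED4L	E893K	893	C-lobe
NED4L	R897Q	897	C-lobe
SMURF2	T641A	641	C-lobe
HECW2	R1191Q	1191	ext-a2
HECW2	F1193V	1193	ext-a2
HECW2	R1330W	1330	N-lobe
HECW2	D1442G	1442	-
HECW2	E1445G	1445	-
HERC1	L4154X	4154	ext-a3
HERC1	G4520E	4520	N-lobe
HERC2	D4267E	4267	ext-a3
TRIP12	R1595Q	1595	N-lobe
TRIP12	S1840L	1840	N-lobe
TRIP12	Q1916X	1916	C-lobe
HUWE1	R3267H	3267	ext-a4
HUWE1	R4013W	4013	ext-a1
HUWE1	R4023C	4023	-
HUWE1	N4075K	4075	-
HUWE1	Y4106C	4106	-
HUWE1	L4157V	4157	-
HUWE1	E4244D	4244	-
HUWE1	R4063Q	4063	N-lobe
HUWE1	R4130Q	4130	-
HUWE1	R4187H	4187	-
HUWE1	R4187C	4187	-
HUWE1	G4229D	4229	-
HUWE1	K4295N	4295	C-lobe
HUWE1	G4310R	4310	-
HACE1	R585W	585	N-lobe
HACE1	Q618fs	618	-
HACE1	P674fs	674	-
HACE1	R748X	748	-
HACE1	L832X	832	C-lobe
HACE1	A861P	861	-
HECTD3	R478C	478	-
AREL1	P779L	779	C-lobe
UBE3B	Q700X	700	N-lobe
UBE3B	G779R	779	N-lobe
UBE3B	Q727P	727	-
UBE3B	R922C	922	-
UBE3B	R997P	997	C-lobe
UBE3B	Q1005P	1005	-
UBE3C	S845F	845	N-lobe
UBE3C	F996C	996	C-lobe
E6AP	I827K	827	C-lobe
E6AP	G870D	870	C-lobe
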