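protein_id	family	uniprot	msa	alphafold	notes
HERC1	HERC	4501-4848	4451-4861	N/A	-
HERC2	HERC	4457-4794	4400-4834	N/A	-
HERC3	HERC	951-1050	681-1050	659-1050	Longer predicted loop and helix
HERC4	HERC	730-1057	689-1057	667-1057	Longer predicted loop and helix
HERC5	HERC	702-1024	659-1024	638-1024	Longer predicted loop and helix
HERC6	HERC	693-1017	650-1022	629-1022	Longer predicted loop and helix
NEDD4	NEDD	984-1318	940-1319	941-1319	PDB 2XBF
NED4L	NEDD	640-974	594-975	595-975	PDB 2ONI
ITCH	NEDD	569-903	527-903	528-903	PDB 3TUG
WWP1	NEDD	588-922	547-922	547-922	PDB 1ND7
WWP2	NEDD	536-870	494-870	494-870	PDB 4Y07
SMURF1	NEDD	420-757	377-757	369-757	Similar prediction
SMURF2	NEDD	414-748	371-748	367-748	PDB 1ZVD
HECW1	NEDD	1271-1606	1226-1606	1223-1606	Similar prediction
HECW2	NEDD	1237-1572	1192-1572	1189-1572	Similar prediction
TRIP12	Other	1885-1992	1561-1992	1558-1992	unique helix orientation PDB 3G1N, 3H1D, 5LP8
HUWE1	Other	4038-4374	3993-4374	N/A	PDB 7MWE
HACE1	Other	574-909	529-909	524-909	Similar prediction
HECTD1	Other	2151-2610	2192-2610	2091-2610	Longer predicted loop and helix
HECTD2	Other	437-776	395-776	377-776	Longer predicted loop and helix
HECTD3	Other	512-857	474-861	451-861	Longer predicted loop and helix
HECTD4	Other	3627-3996	3570-3996	N/A	-
UBR5	Other	2462-2799	2395-2799	N/A	-
AREL1	Other	483-823	439-823	439-823	PDB 6JX5
G2E3	Other	371-698	341-706	345-706	Similar prediction
UBE3B	Other	702-1068	659-1068	650-1068	Longer predicted loop and helix
UBE3C	Other	744-1083	695-1083	695-1083	PDB 6K2C
E6AP	Other	776-875	500-875	486-875	Longer predicted loop and helix
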