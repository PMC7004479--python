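family	protein_name	accession	thailand_pct	indonesia_pct
KSPI	Kunitz-type serine protease inhibitor 2	P00990	1.4
KSPI	Kunitz-type serine protease inhibitor B5	A8Y7P5	0.66
KSPI	Kunitz-type serine protease inhibitor B6	A8Y7P6	1.93
KSPI	Kunitz-type serine protease inhibitor C1	A8Y7N4	8.43
KSPI	Kunitz-type serine protease inhibitor C2	A8Y7N5	0.81
KSPI	Kunitz-type serine protease inhibitor C4	A8Y7N7	3.75
KSPI	Kunitz-type serine protease inhibitor C6	A8Y7N9	5.04
KSPI	Kunitz-type serine protease inhibitor DrKIn-II	H6VC06	0.36
PLA2	Acidic phospholipase A2 Drk-a1	A8CG86		4.95
PLA2	Acidic phospholipase A2 RV-7	P31100	21.27	17.12
PLA2	Basic phospholipase A2	B3RFI7	12.63	21.41
PLA2	Basic phospholipase A2 beta-bungarotoxin A1 chain	P00617	0.1
PLA2	Basic phospholipase A2 RV-4	Q02471	0.1
PLA2	Phospholipase A2	B2YHV5	1.13
PLA2	Phospholipase A2 1	P86529	2.69	4.89
snaclec	Factor X activator light chain 1	CL290.Contig28_NnSL	1.58
snaclec	Factor X activator light chain 2	K9JDJ1	0.25
snaclec	P31 alpha subunit	K9JBU9	0.19
snaclec	P31 alpha subunit	CL1101.Contig2_DrSL	3.54
snaclec	P31 beta subunit	K9JBV3	0.35
snaclec	P31 beta subunit	K9JDF6	0.23
snaclec	P68 alpha subunit	K9JBV0	1.01
snaclec	P68 alpha subunit	K9JDF2		0.44
snaclec	P68 alpha subunit	CL2900.Contig2_NnSL	0.03
snaclec	RVV-X light chain 1	A0A2H4Z2X7	1.35
snaclec	Snaclec 3	Q4PRD0	0.32	0.09
snaclec	Snaclec 4	Q4PRC9	0.02
snaclec	Snaclec coagulation factor X-activating enzyme light chain 1	Q4PRD1	1.38	0.21
snaclec	Snaclec coagulation factor X-activating enzyme light chain 2	Q4PRD2	0.38	0.29
SVSP	Alpha-fibrinogenase-like	E5L0E3	0.95	0.47
SVSP	Beta-fibrinogenase	E0Y419	1.41
SVSP	Beta-fibrinogenase-like	E5L0E4	3.22	0.18
SVSP	Factor V activator RVV-V gamma	P18965	5.11	4.5
SVSP	Factor V activator RVV-V gamma	Unigene26743_DrSL	0.32
SVSP	Factor V activator RVV-V gamma	Unigene26743_EsM		1.54
SVSP	RVV-V gamma-like protein precursor	CL3102.Contig2_NnSL	0.31	0.04
SVSP	Serine beta-fibrinogenase	CL2958.Contig2_DrSL	0.4	3.97
SVSP	Serine protease VLSP-1	CL310.Contig24_NnSL	0.32
SVSP	Serine protease VLSP-3	E0Y420	4.27	0.34
SVSP	Venom serine proteinase-like protein 2	Q9PT40	1.76	11.37
SVMP	Coagulation factor X-activating enzyme heavy chain	Q7LZ61	3.04	1.83
SVMP	Factor X light activator chain 2	T1P647		0.32
LAAO	L-amino-acid oxidase	G8XQX1		0.53
LAAO	L-amino-acid oxidase	P0C2D7		0.94
svVEGF	Snake venom vascular endothelial growth factor toxin VR-1	P67861	2.46
svVEGF	Snake venom vascular endothelial growth factor toxin VR-1'	P0DL42	2.96
svNGF	Venom nerve growth factor 1	V9I1K1	0.52	0.85
5NUC	5'-nucleotidase	U3T7C6	0.54
5NUC	5'-nucleotidase	W8EFS0	0.39
5NUC	Snake venom 5'-nucleotidase	CL3322.Contig1_DrSL		0.18
5NUC	Snake venom 5'-nucleotidase	CL3322.Contig2_DrSL	0.39
5NUC	Snake venom 5'-nucleotidase OS	CL2941.Contig2_EcSL	0.53
PDE	Phosphodiesterase	U3TBJ5	0.08	0.6
PDE	Phosphodiesterase 1	CL3655.Contig2_DrSL	0.08	0.29
DIS	Disintegrin jerdostatin	Q7ZZM2		6.21
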