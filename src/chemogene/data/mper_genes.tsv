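gene_id	family	rpkm	signal_peptide	aa_len	orf_bp	location	accession
MperOBP2	OBP	383	1-19	244	732	105 (340085..345920,-)	MG356454
MperOBP3	OBP	135	1-23	142	426	21 (798710..815519,+)	MG356455
MperOBP4	OBP	21	1-22	200	600	300 (285472..288740,+)	MG356456
MperOBP5	OBP	99	1-25	222	666	4 (1732552..1743198,-)	MG356457
MperOBP6	OBP	73	1-19	216	648	77 (15902..21431,-)	MG356458
MperOBP7	OBP	65	1-24	150	450	21 (790748..798189,+)	MG356459
MperOBP8	OBP	33	1-18	162	486	21 (816539..821387,+)	MG356460
MperOBP9	OBP	19	1-24	167	501	422 (21121..26183,+)	MG356461
MperOBP10	OBP	8	1-24	144	432	47 (690675..693525,-)	MG356462
MperCSP1	CSP	16	none	286	858	112 (593787..605068,-)	MG356463
MperCSP2	CSP	330	1-20	132	396	55 (285362..286497,-)	MG356464
MperCSP4	CSP	286	1-22	146	438	112 (578383..579415,-)	MG356465
MperCSP5	CSP	609	1-19	140	420	10 (1364996..1366765,-)	MG356466
MperCSP6	CSP	91	1-21	132	396	112 (615905..617608,-)	MG356467
MperCSP7	CSP	40	1-24	156	468	910 (34801..42428,-)	MG356468
MperCSP8	CSP	38	1-37	164	492	10 (1379554..1382877,-)	MG356469
MperCSP9	CSP	330	1-22	163	489	55 (282954..285123,+)	MG356470
MperCSP10	CSP	3	1-21	151	453	420 (101975..105884,-)	MG356471
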