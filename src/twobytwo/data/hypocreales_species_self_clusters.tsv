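cluster_id	swissprot_hit	protein_name	members
cluster10663	OPS1	Orsellinic acid synthase	Bb_ERL836|KAF1732856.1; Bb_JEF-350|KAH8713103.1; Bb_JEF-350|KAH8713104.1
cluster11284	OPS7	Oxidoreductase OpS7	Bb_ERL836|KAF1732862.1; Bb_JEF-350|KAH8713097.1
cluster11283	J5J924	MFS transporter OpS2	Bb_ERL836|KAF1732858.1; Bb_JEF-350|KAH8713102.1
cluster11282	OPS3	Oosporein cluster regulator OpS3	Bb_ERL836|KAF1732857.1; Bb_JEF-350|KAH8713101.1
cluster12734		No hit	Cm_34164|ATY65128.1; Cm_CM01|EGX93064.1
cluster12735	O05502	Uncharacterized protein YdhJ	Cm_34164|ATY65129.1; Cm_CM01|EGX93065.1
cluster12736		No hit	Cm_34164|ATY65134.1; Cm_CM01|EGX93066.1
cluster13200	P29138	Cuticle-degrading protease PR1	Mb_3297|KID60942.1; Mb_4556|QLI68484.1
cluster13207	L8G6I7	Subtilisin-like protease 1	Mb_3297|KID61215.1; Mb_4556|QLI74370.1
cluster13386	L8GD75	Subtilisin-like protease 3	Mb_3297|KID66974.1; Mb_4556|QLI70477.1
cluster13323	A0A0B4GDU5	Scytalone dehydratase-like protein Arp1	Mb_3297|KID65390.1; Mb_4556|QLI69143.1
cluster13990	D4AX50	Subtilisin-like protease 8	Mb_3297|KID76020.1; Mb_4556|QLI67847.1
cluster10467	E9F8M0	Transmembrane transporter swnT	Mb_3297|KID64719.1; Mb_3297|KID73970.1; Mb_4556|QLI68254.1; Mb_4556|QLI74702.1
cluster13587	D4AU27	Swainsonine transporter swnT	Mb_3297|KID72725.1; Mb_4556|QLI71645.1
cluster10517	D4AU26	Dioxygenase swnH1	Mb_3297|KID73870.1; Mb_3297|KID73969.1; Mb_4556|QLI67169.1; Mb_4556|QLI67423.1
cluster13740	E9F8M4	Dioxygenase swnH2	Mb_3297|KID73974.1; Mb_4556|QLI68135.1
cluster14860	G0R6S7	Short chain dehydrogenase sor7	Tr_CBS999|TreeseiCBS999.97_006656-T1; Tr_QM6a|TreeseiQM6a_006735-T1
cluster12871	A0A024FA41	Fatty acid hydroxylase vlmA	Ef_Fl1|QPG93928.1; Ef_RoseCity|EfestucaeRoseCity_000440-T1
cluster13039	A0A024F910	Nonribosomal peptide synthetase vlms	Ef_Fl1|QPH06327.1; Ef_RoseCity|EfestucaeRoseCity_000031-T1
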