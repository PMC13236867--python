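strain_id	species_id	family_id	display_name	is_reference
Cj_Apopka97	Cordyceps_javanica	Cordycipitaceae	Cordyceps javanica Apopka 97	1
Cj_IJ2G	Cordyceps_javanica	Cordycipitaceae	Cordyceps javanica IJ2G	0
Cf_2679	Cordyceps_fumosorosea	Cordycipitaceae	Cordyceps fumosorosea ARSEF 2679	0
Cf_grCorFumo1	Cordyceps_fumosorosea	Cordycipitaceae	Cordyceps fumosorosea grCorFumo1	1
Cm_34164	Cordyceps_militaris	Cordycipitaceae	Cordyceps militaris ATCC 34164	1
Cm_CM01	Cordyceps_militaris	Cordycipitaceae	Cordyceps militaris CM01	0
Cc_FRD24	Cordyceps_cateniannulata	Cordycipitaceae	Cordyceps cateniannulata FRD 24	1
Cc_MBC234	Cordyceps_cateniannulata	Cordycipitaceae	Cordyceps cateniannulata MBC 234	0
Bb_ERL836	Beauveria_bassiana	Cordycipitaceae	Beauveria bassiana ERL836	1
Bb_JEF-350	Beauveria_bassiana	Cordycipitaceae	Beauveria bassiana JEF-350	0
Mb_4556	Metarhizium_brunneum	Clavicipitaceae	Metarhizium brunneum ARSEF 4556	1
Mb_3297	Metarhizium_brunneum	Clavicipitaceae	Metarhizium brunneum ARSEF 3297	0
Ef_Fl1	Epichloe_festucae	Clavicipitaceae	Epichloe festucae Fl1	1
Ef_RoseCity	Epichloe_festucae	Clavicipitaceae	Epichloe festucae RoseCity	0
Tr_CBS999	Trichoderma_reesei	Hypocreaceae	Trichoderma reesei CBS999.97	1
Tr_QM6a	Trichoderma_reesei	Hypocreaceae	Trichoderma reesei QM6a	0
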