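# NPC1 protein domain model (isoform 1, 1278 aa): 13 transmembrane domains
# (TD1-TD13) interleaved with 14 luminal/cytoplasmic segments labelled
# alphabetically in sequence order (LDA, CDB, LDC, ... CDN).  The
# sterol-sensing domain (SSD) comprises TD3-TD7.  Boundaries are
# APPROXIMATE: they follow the membrane topology of the protein, with
# CDL (29 aa), CDN (30 aa), CDJ (7 aa), TD4 and TD7 (20 aa) lengths fixed
# by the per-domain burden statistics this model must support.
# protein_length=1278
name	category	start	end	in_ssd
LDA	luminal	23	264	false
TD1	transmembrane	265	285	false
CDB	cytoplasmic	286	351	false
TD2	transmembrane	352	372	false
LDC	luminal	373	619	false
TD3	transmembrane	620	640	true
CDD	cytoplasmic	641	654	false
TD4	transmembrane	655	674	true
LDE	luminal	675	684	false
TD5	transmembrane	685	705	true
CDF	cytoplasmic	706	714	false
TD6	transmembrane	715	735	true
LDG	luminal	736	760	false
TD7	transmembrane	761	780	true
CDH	cytoplasmic	781	800	false
TD8	transmembrane	801	821	false
LDI	luminal	822	1097	false
TD9	transmembrane	1098	1118	false
CDJ	cytoplasmic	1119	1125	false
TD10	transmembrane	1126	1146	false
LDK	luminal	1147	1149	false
TD11	transmembrane	1150	1170	false
CDL	cytoplasmic	1171	1199	false
TD12	transmembrane	1200	1220	false
LDM	luminal	1221	1227	false
TD13	transmembrane	1228	1248	false
CDN	cytoplasmic	1249	1278	false
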