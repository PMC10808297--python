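# Genus-level soil nematode trait reference.
# Compiled by the package authors from the public Nemaplex trait compendium
# (feeding group and c-p class after Yeates et al. 1993 / Bongers 1990);
# fresh_weight is the mean individual fresh body mass in micrograms.
# Columns: genus, trophic_group (BF/FF/PP/OP), cp_class (1-5),
# fresh_weight (µg), op_code (Om/Ca override for OP genera only).
genus	trophic_group	cp_class	fresh_weight	op_code
Rhabditis	BF	1	2.80
Panagrolaimus	BF	1	1.15
Diploscapter	BF	1	0.60
Mesorhabditis	BF	1	0.95
Acrobeloides	BF	2	0.40
Acrobeles	BF	2	1.30
Cephalobus	BF	2	0.70
Eucephalobus	BF	2	0.55
Chiloplacus	BF	2	0.85
Plectus	BF	2	1.20
Prismatolaimus	BF	3	0.60
Alaimus	BF	4	0.40
Aphelenchus	FF	2	0.60
Aphelenchoides	FF	2	0.30
Ditylenchus	FF	2	0.45
Filenchus	FF	2	0.30
Miculenchus	FF	2	0.20
Tylencholaimus	FF	4	0.50
Paratylenchus	PP	2	0.11
Pratylenchus	PP	3	0.28
Helicotylenchus	PP	3	0.80
Tylenchorhynchus	PP	3	0.60
Hoplotylus	PP	3	0.50
Xiphinema	PP	5	11.00
Longidorus	PP	5	15.00
Mesodorylaimus	OP	4	1.60	Om
Eudorylaimus	OP	4	3.00	Om
Aporcelaimellus	OP	5	10.50	Om
Mononchus	OP	4	6.50	Ca
Prionchulus	OP	4	8.00	Ca
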