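# Alfalfa (Medicago sativa) miR166 counts from dedicated small-RNA and degradome
# sequencing rather than miRBase; kept separate from the cross-species census and
# excluded from its summaries by default.
species_name	abbreviation	division	clade_family	monocot_dicot	n_precursor	n_mature
Medicago sativa	msa	angiosperm	Leguminosae	dicot	4	8
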