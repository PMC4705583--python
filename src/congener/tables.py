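"""Reference figures from the three-species *Xiphophorus* comparison.

Published summary tables for the genome models this toolkit emulates
(X. couchianus and X. hellerii built against the X. maculatus reference):
per-category polymorphism-effect counts, transcriptome transfer counts and
chromosome-level assembly sizes.  They serve as worked-example inputs for
the summarization routines and as fixed points for validation; nothing in
the toolkit derives them.
"""

#: polymorphism-effect counts per annotation category, X. couchianus vs
#: the reference genome (effects, not variants, are the counting unit)
EFFECT_COUNTS_XCOUCHIANUS: dict[str, int] = {
    "downstream": 1_542_508,
    "codon_indel": 2_467,
    "exon": 211,
    "intergenic": 5_007_423,
    "intron": 4_103_306,
    "non_synonymous_coding": 84_752,
    "splice_site": 35_823,
    "start_lost": 116,
    "stop_gained": 805,
    "stop_lost": 314,
    "synonymous_coding": 140_717,
    "upstream": 1_564_218,
    "utr3": 243_474,
    "utr5": 51_921,
}

#: total effects reported for the X. couchianus comparison
EFFECT_TOTAL_XCOUCHIANUS = 12_778_055

EFFECT_COUNTS_XHELLERII: dict[str, int] = {
    "downstream": 1_942_329,
    "codon_indel": 2_863,
    "exon": 230,
    "intergenic": 6_594_737,
    "intron": 5_358_720,
    "non_synonymous_coding": 101_178,
    "splice_site": 44_523,
    "start_lost": 133,
    "stop_gained": 945,
    "stop_lost": 445,
    "synonymous_coding": 174_526,
    "upstream": 1_937_840,
    "utr3": 304_241,
    "utr5": 64_017,
}

EFFECT_TOTAL_XHELLERII = 16_526_727

#: gene models in the reference annotation and the number successfully
#: transferred to each new genome
GENE_MODELS = {
    "reference": 20_498,
    "x_couchianus": 20_300,
    "x_hellerii": 20_325,
}

#: chromosome-level assembly totals in Mb
CHROMOSOME_TOTAL_MB = {
    "x_maculatus": 724,
    "x_couchianus": 708,
    "x_hellerii": 734,
}
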