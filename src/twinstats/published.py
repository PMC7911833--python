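"""Published summary counts from the Australian pediatric pain twin-family
questionnaire study (1016 evaluable families; 504 MZ and 513 DZ pairs).

These printed counts are sufficient inputs for the unadjusted similarity
analyses: casewise concordance, pair correlation, pair odds ratio and the
MZ-vs-DZ likelihood-ratio tests are all functions of the per-zygosity pair
counts alone, and prevalence of the individual-level affected/unaffected
counts.  They serve as validation fixtures for the estimators.
"""

from twinstats.cohort import PairCounts

#: (N_c, N_d, N_00) twin-pair counts per (condition, zygosity)
PAIR_COUNTS = {
    ("gp", "MZ"): (61, 74, 368),
    ("gp", "DZ"): (41, 96, 376),
    ("migraine", "MZ"): (16, 38, 449),
    ("migraine", "DZ"): (8, 53, 452),
    ("headache", "MZ"): (33, 75, 395),
    ("headache", "DZ"): (22, 89, 402),
    ("rap", "MZ"): (33, 73, 396),
    ("rap", "DZ"): (17, 88, 407),
    ("lbp", "MZ"): (19, 41, 213),
    ("lbp", "DZ"): (10, 59, 308),
    ("pp", "MZ"): (14, 40, 448),
    ("pp", "DZ"): (6, 47, 459),
}

#: (affected, unaffected) twin-individual counts per (condition, zygosity);
#: singleton responders included, which is why totals are odd for some cells
TWIN_PREVALENCE_COUNTS = {
    ("gp", "MZ"): (196, 811),
    ("gp", "DZ"): (178, 848),
    ("migraine", "MZ"): (70, 937),
    ("migraine", "DZ"): (69, 957),
    ("headache", "MZ"): (141, 866),
    ("headache", "DZ"): (133, 893),
    ("rap", "MZ"): (140, 866),
    ("rap", "DZ"): (123, 902),
    ("lbp", "MZ"): (79, 470),
    ("lbp", "DZ"): (80, 677),
    ("pp", "MZ"): (68, 938),
    ("pp", "DZ"): (59, 966),
}


def pair_counts(condition: str, zygosity: str) -> PairCounts:
    """Published pair counts as a :class:`PairCounts` instance."""
    nc, nd, n00 = PAIR_COUNTS[(condition, zygosity)]
    return PairCounts(zygosity, condition, nc, nd, n00)
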