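"""Published reference data from a camera-validated study of pied flycatcher
(*Ficedula hypoleuca*) nestling diet metabarcoding.

These small tables are inputs for reproducing the study's desk-checkable
statistics: the COI primer set whose longest member fixes the 25 bp per-end
primer truncation, the per-order relative read abundances from the
four-replicate DNA-extraction x primer comparison, and the gizzard versus
intestine frequency-of-occurrence comparison for common genera.
"""

from __future__ import annotations

import pandas as pd

#: Generic invertebrate COI primers and their host-avoiding modified
#: versions.  The longest (25 bp) sets the per-end primer truncation width.
PRIMERS = {
    "LCO1490": "GGTCAACAAATCATAAAGATATTGG",
    "LCO1490_5T": "GGTCTACAAATCATAAAGATATTGG",
    "HCO1777": "ACTTATATTGTTTATACGAGGGAA",
    "HCO1777_15T": "ACTTATATTATTTATACGAGGGAA",
}


def max_primer_length() -> int:
    """Length of the longest primer: the per-end truncation width."""
    return max(len(s) for s in PRIMERS.values())


#: Per-order relative read abundance (percent) for the pair-wise comparison
#: of original vs modified primers under two DNA-extraction kits applied to
#: two samples (S1, S2).  Column pairs are (original, modified).
_RRA_ROWS = [
    ("Araneae",        3.01,  8.46,  1.82,  7.98,  2.09,  5.99,  0.03,  0.14),
    ("Coleoptera",     0.92,  0.08,  0.81,  0.58, 46.11, 23.28,  1.73,  0.36),
    ("Collembola",     0.51,  2.10,  0.55,  1.71,  0.00,  0.00,  0.00,  0.00),
    ("Diplostraca",    0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  1.11,  0.00),
    ("Diptera",        2.08,  3.71,  7.56,  5.14,  2.95,  8.09,  0.84,  0.20),
    ("Hemiptera",     53.74, 47.24, 64.20, 58.17,  2.38,  1.60,  1.11,  0.11),
    ("Hymenoptera",   11.47, 13.33,  8.91, 10.43, 37.43, 55.46, 90.35, 98.96),
    ("Isopoda",        4.98,  3.88,  5.85,  3.37,  0.00,  0.00,  0.00,  0.00),
    ("Lepidoptera",   21.81, 19.41,  9.53, 12.40,  0.02,  0.11,  0.40,  0.08),
    ("Mesostigmata",   1.43,  1.40,  0.55,  0.04,  0.60,  0.00,  4.31,  0.01),
    ("Neuroptera",     0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00),
    ("Orthoptera",     0.00,  0.00,  0.00,  0.00,  0.00,  0.05,  0.00,  0.00),
    ("Prostigmata",    0.01,  0.00,  0.00,  0.00,  6.57,  4.93,  0.06,  0.13),
    ("Psocoptera",     0.01,  0.40,  0.09,  0.14,  0.00,  0.00,  0.00,  0.00),
    ("Thysanoptera",   0.03,  0.00,  0.12,  0.05,  0.00,  0.00,  0.00,  0.00),
    ("Trichoptera",    0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00,  0.00),
    ("Trombidiformes", 0.00,  0.00,  0.00,  0.00,  1.86,  0.49,  0.06,  0.01),
]

#: The four replicate pairs in column order, with the published squared
#: Pearson correlations between original and modified primers.
PRIMER_COMPARISON_PAIRS = (
    ("S1 PowerSoil", 0.98),
    ("S1 PureLink", 0.98),
    ("S2 PowerSoil", 0.72),
    ("S2 PureLink", 0.99),
)


def primer_comparison_rra() -> pd.DataFrame:
    """Per-order RRA (percent) with a two-level (pair, primer) column index."""
    cols = pd.MultiIndex.from_tuples(
        [
            (pair, primer)
            for pair, _ in PRIMER_COMPARISON_PAIRS
            for primer in ("original", "modified")
        ]
    )
    df = pd.DataFrame(
        [row[1:] for row in _RRA_ROWS],
        index=[row[0] for row in _RRA_ROWS],
        columns=cols,
    )
    df.index.name = "order"
    return df


#: Gizzard vs intestine frequency of occurrence for the 17 common genera
#: (those occurring in >= 3 samples of at least one sample type).
_FOO_ROWS = [
    ("Kleidocerys",   8, 8),
    ("Formica",       6, 7),
    ("Boletina",      8, 7),
    ("Strophosoma",   7, 6),
    ("Lochmaea",      4, 5),
    ("Procladius",    4, 5),
    ("Pollenia",      6, 5),
    ("Aedes",         8, 5),
    ("Limonia",       2, 4),
    ("Pterostichus",  4, 4),
    ("Hemerobius",    1, 3),
    ("Harpocera",     2, 3),
    ("Limnephilus",   2, 3),
    ("Phortica",      3, 3),
    ("Campylocheta",  4, 3),
    ("Chironomus",    4, 3),
    ("Gilpinia",      4, 3),
]


def gizzard_intestine_foo() -> tuple[dict[str, int], dict[str, int]]:
    """(gizzard FOO, intestine FOO) per genus for the digestion comparison."""
    return (
        {g: a for g, a, _ in _FOO_ROWS},
        {g: b for g, _, b in _FOO_ROWS},
    )
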