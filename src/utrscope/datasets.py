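"""Bundled reference data: the ABCA1 vertebrate ortholog family.

Small published observations for the ABCA1 gene's 5'UTR across 15
representative vertebrates, bundled so examples and regression tests run
without any database access:

* ``abca1_uorf_table`` — the conserved uORF called in each species
  (1-based, stop-inclusive start/stop from the transcription start site),
  its length in nt and aa, the predicted peptide, and the annotated
  main-ORF start;
* ``abca1_context_table`` — up-to-21-nt start-codon contexts (9 bases
  upstream, the ATG, 9 bases downstream; shorter when the ATG sits close
  to the 5' end) for the uORF's uATG and the main ORF's sATG;
* ``abca1_human_hairpins`` — closing-pair intervals of the seven hairpin
  loops predicted in the human 5'UTR, positions from the TSS.
"""

from __future__ import annotations

import pandas as pd

# species, uorf_start, uorf_stop, len_nt, len_aa, peptide, morf_start
_UORF_ROWS = [
    ("Human", 307, 417, 111, 36, "MTSHGVPAVSSGRCLPGLPSHTLGVLAEGTWLVGLS", 396),
    ("Macaque", 364, 474, 111, 36, "MTSHGIPAVSSGRCLPGLLSHTLWVLAEGTWLVGLS", 453),
    ("Mouse lemur", 314, 424, 111, 36, "MTSHSIPAVSSGHCLPGLLSHTLWVPAEVTWLVGPS", 403),
    ("Rabbit", 327, 440, 114, 37, "MTSHSGFATSSGRCLQGRATSRLPWVPAEVTWPAGLS", 419),
    ("Mouse", 224, 319, 96, 31, "MTSHRVTALCSGCSLQGSRAADAGRCGCRLW", 321),
    ("Squirrel", 279, 365, 87, 28, "MTSHSVCCELRPVPPGLLSHTQVALGAG", 372),
    ("Cat", 304, 393, 90, 29, "MTSHSVPAVSCCCCLQKLLSHTQVAAAAG", 400),
    ("Armadillo", 304, 399, 96, 31, "MTSHSVPAVSSGHCPHGLPTSHTQVAWARLR", 401),
    ("Tasmanian devil", 4, 66, 63, 20, "MTSHSVPAQRYLCSLHYLPG", 96),
    ("Opossum", 333, 395, 63, 20, "MTSHGVLAQCCLCSLHYLLD", 425),
    ("Platypus", 54, 131, 78, 25, "MTSHSVPAVCCCHCPCHTRGAVPAC", 138),
    ("Chicken", 135, 200, 66, 21, "MPSHNVLVVYCCCCTKGRRHC", 207),
    ("Flycatcher", 4, 60, 57, 18, "MPGHNICTVLLLLHKESF", 77),
    ("Anole lizard", 221, 271, 51, 16, "MTSHSSSAVCCFHPRC", 295),
    ("Coelacanth", 245, 274, 30, 9, "MSDNNIPAA", 297),
]

# species, uORF uATG context, mORF sATG context
_CONTEXT_ROWS = [
    ("Human", "AAACAGTTAATGACCAGCCAC", "TGAGGGAACATGGCTTGTTGG"),
    ("Macaque", "AAACAGTTAATGACCAGCCAC", "TGAGGGAACATGGCTTGTTGG"),
    ("Mouse lemur", "AAGCAGTTAATGACCAGCCAC", "TGAGGTGACATGGCTTGTTGG"),
    ("Rabbit", "AAGCAGTTAATGACCAGCCAC", "TGAGGTAACATGGCCTGCTGG"),
    ("Mouse", "AAACAGTTAATGACCAGCCAC", "TGTGGTGACATGGCTTGTTGG"),
    ("Squirrel", "AAACAGTTAATGACCAGCCAC", "TGAGGTAACATGGCTTATTGG"),
    ("Cat", "AAACAGTTAATGACCAGCCAC", "TGAGGAAACATGGCTTACTGG"),
    ("Armadillo", "AAACAGTTAATGACCAGCCAC", "TGAGGTAACATGGCTTGCTGG"),
    ("Tasmanian devil", "TTAATGACCAGCCAC", "TGAGGAAAGATGGCTTTTTGG"),
    ("Opossum", "AAGCAGTTAATGACCAGCCAC", "TGAGGAGAGATGGCCTTTTGG"),
    ("Platypus", "TTCCAGTTAATGACCAGCCAC", "TGAGGAAAGATGGCTTTTTGG"),
    ("Chicken", "CCGGAGTTAATGCCCAGCCAT", "TGAAGAACGATGGCATTTTGG"),
    ("Flycatcher", "TTAATGCCTGGCCAC", "TGAAGGAAGATGGCTTTCTGG"),
    ("Anole lizard", "GAGGAGTTGATGACCAGCCAC", "AGAAGGAAGATGGCCTTCTGG"),
    ("Coelacanth", "AAAAAGTTAATGTCCGACAAC", "TGGGAAAAGATGACTTTCTGG"),
]

# closing-pair intervals of the seven human 5'UTR hairpin loops
ABCA1_HUMAN_HAIRPINS = [
    (21, 53), (66, 115), (123, 154), (156, 225), (229, 277), (286, 295), (312, 388),
]

# human variant survey: distinct 5'UTR positions carrying annotated variants
# and how many of them fall inside the conservation hot spots
ABCA1_HUMAN_VARIANT_POSITIONS = 161
ABCA1_HUMAN_VARIANTS_IN_HOTSPOTS = 39


def abca1_uorf_table() -> pd.DataFrame:
    return pd.DataFrame(
        _UORF_ROWS,
        columns=[
            "species", "uorf_start", "uorf_stop", "len_nt", "len_aa",
            "peptide", "morf_start",
        ],
    )


def abca1_context_table() -> pd.DataFrame:
    return pd.DataFrame(
        _CONTEXT_ROWS, columns=["species", "uorf_context", "morf_context"]
    )
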