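"""Reference oligonucleotides for the SALL4 ZFC4 HT-SELEX library design.

These are the single-stranded random-library templates and the PCR /
sequencing primers of the library architecture this toolkit models: a
20 bp random insert flanked by constant regions, amplified with Library
FW/RV into an 83 bp double-stranded cycle-0 library, then converted with
Seqlib FW and one of 21 barcoded Seqlib RV primers into a 144 bp
Illumina library carrying P5/P7 adapters and a unique 8 bp i7 index.
"""

from __future__ import annotations

from selexkit.construct import BarcodeTable, LibraryConstruct, Primer, extract_barcode

# Single-stranded templates: 21 nt constant 5' flank, 20 nt random
# insert, 22 nt constant 3' flank (63 nt total). The three libraries
# share a design and act as independent technical replicates.
RANDOM_LIBRARY_TEMPLATE = (
    "TACACGACGCTCTTCCGATCT" + "N" * 20 + "AGATCGGAAGAGCACACGTCTG"
)

RANDOM_LIBRARY_TEMPLATES = {
    "Random library 1": RANDOM_LIBRARY_TEMPLATE,
    "Random library 2": RANDOM_LIBRARY_TEMPLATE,
    "Random library 3": RANDOM_LIBRARY_TEMPLATE,
}

LIBRARY_FW = Primer("Library FW", "ACACTCTTTCCCTACACGACGCTCTTCCGATCT")
LIBRARY_RV = Primer("Library RV", "CTGGAGTTCAGACGTGTGCTCTTCCGATCT")

SEQLIB_FW = Primer("Seqlib FW", "AATGATACGGCGACCACCGAGATCTACACTCTTTCCCTACACGACGC")

# Every Seqlib RV primer is P7 flank + unique 8 bp i7 barcode + constant
# 3' region annealing to the SELEX library.
SEQLIB_RV_FIVE_FLANK = "CAAGCAGAAGACGGCATACGAGAT"
SEQLIB_RV_THREE_FLANK = "GTGACTGGAGTTCAGACGTGTGCTCT"

_SEQLIB_RV_BARCODES = [
    "CCAAGTCC",
    "CAGTGGAT",
    "CTAGCTTG",
    "GAGTCCAA",
    "TCCGGATT",
    "AAGGTACC",
    "GGAACGTT",
    "GGCCTCAT",
    "ATCTTAGT",
    "CTTCACGG",
    "TCCTGTAA",
    "CCTCGGTA",
    "ATGAGGCT",
    "GCAGAATC",
    "TGTCGTAG",
    "TAGAGCGC",
    "GGTTCACC",
    "CATTGTTG",
    "ACGCCGCA",
    "GTATTATG",
    "AGCGAGCT",
]

SEQLIB_RV_PRIMERS = [
    Primer(f"Seqlib RV {i}", SEQLIB_RV_FIVE_FLANK + bc + SEQLIB_RV_THREE_FLANK)
    for i, bc in enumerate(_SEQLIB_RV_BARCODES, start=1)
]

# Construct description of the random library (insert coordinates
# relative to the single-stranded template).
RANDOM_LIBRARY_CONSTRUCT = LibraryConstruct(
    five_prime_flank="TACACGACGCTCTTCCGATCT",
    insert_length=20,
    three_prime_flank="AGATCGGAAGAGCACACGTCTG",
    description="random SELEX library: 20 bp random insert with constant flanks",
)


def seqlib_barcode_table() -> BarcodeTable:
    """Barcode table of the 21 Seqlib RV primers, keyed RV01..RV21.

    Barcodes are re-derived from the primer sequences (flank removal)
    rather than restated, so the table always reflects the primers.
    """
    entries = {}
    for i, primer in enumerate(SEQLIB_RV_PRIMERS, start=1):
        entries[f"RV{i:02d}"] = extract_barcode(
            primer, SEQLIB_RV_FIVE_FLANK, SEQLIB_RV_THREE_FLANK
        )
    return BarcodeTable(entries)


OLIGO_REGISTRY: dict[str, str] = {
    **RANDOM_LIBRARY_TEMPLATES,
    LIBRARY_FW.name: LIBRARY_FW.seq,
    LIBRARY_RV.name: LIBRARY_RV.seq,
    SEQLIB_FW.name: SEQLIB_FW.seq,
    **{p.name: p.seq for p in SEQLIB_RV_PRIMERS},
}
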