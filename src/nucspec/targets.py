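"""Published zinc-finger nuclease target sequences and reported aggregates.

These are the fixed inputs of the CCR5/CCR2 discrimination study this package
re-analyses: the SELEX library architecture, the 12-nt half-site bound by the
3' ("right") CCR5 ZFN monomer together with its single-mismatch CCR2
homologue, and the published aggregate off-target activities of the ZFN pairs
profiled by IDLV capture.
"""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of mismatched positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def count_matches(a: str, b: str) -> int:
    """Position-wise matches between two equal-length targets."""
    return len(a) - hamming(a, b)


# SELEX library oligo: 24-nt fixed flanks around a 22-nt randomized core.
SELEX_FLANK5 = "CAGGGATCCATGCACTGTACGCCC"
SELEX_FLANK3 = "GGGCCACTTGACTGCGGATCCTGG"
SELEX_VARIABLE_LENGTH = 22

# 12-nt half-site of the published 3' (right) CCR5 ZFN monomer,
# 5'-AAA-CTG-CAA-AAG-3', and the CCR2 homologue in which the 3'-most
# triplet reads AAA instead of AAG (the single discriminatory base).
CCR5_RIGHT_TARGET = "AAACTGCAAAAG"
CCR2_RIGHT_TARGET = "AAACTGCAAAAA"
# Index (0-based) of the discriminatory base within the right half-site.
RIGHT_DISCRIMINATORY_POSITION = 11

# Aggregate off-target activity (% indels summed over statistically active
# off-target loci) per ZFN pair, and the number of active sites, as reported
# from the IDLV-capture screens.
AGGREGATE_OFFTARGET_PERCENT = {
    "8266:20505": 33.3,   # previously published pair, 9 active sites
    "46693:46696": 21.2,  # 11 active sites
    "46693:46697": 6.6,   # 10 active sites
    "46698:46705": 1.5,   # 4 active sites
    "46700:46705": 0.5,   # 3 active sites
}
N_ACTIVE_OFFTARGET_SITES = {
    "8266:20505": 9,
    "46693:46696": 11,
    "46693:46697": 10,
    "46698:46705": 4,
    "46700:46705": 3,
}
PUBLISHED_PAIR = "8266:20505"
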