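"""SELEX specificity profiling for zinc-finger candidates.

Reads from an in-vitro selection pool are filtered for exact library
structure (correct length and exact fixed flanks), subsampled, and summarized
as a position frequency matrix (PFM) over the variable region. Because the
library's fixed flanks pin the register of the variable region, the PFM is
built directly by column counting; the alignment step then orients and trims
the matrix onto the intended target, searching all offsets on both strands.
Discrimination at the bases distinguishing an on-target from its homologue is
reported as per-position base percentages over the aligned reads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .targets import revcomp

BASE_ORDER = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass(frozen=True)
class SelexLibrarySpec:
    """Fixed library architecture: flank5 + N^variable_length + flank3."""

    flank5: str
    flank3: str
    variable_length: int
    intended_target: str = ""

    def __post_init__(self) -> None:
        for fl in (self.flank5, self.flank3):
            if not fl or any(b not in "ACGT" for b in fl):
                raise ValueError(f"flank must be nonempty ACGT, got {fl!r}")
        if self.variable_length <= 0:
            raise ValueError("variable_length must be positive")

    @property
    def read_length(self) -> int:
        return len(self.flank5) + self.variable_length + len(self.flank3)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base frequencies (rows A, C, G, T; columns sum to 1)."""

    frequencies: np.ndarray  # shape (4, L)
    n_reads: int
    pseudocount: float

    def __post_init__(self) -> None:
        f = self.frequencies
        if f.shape[0] != 4:
            raise ValueError("PFM must have 4 rows")
        if np.any(f < 0) or not np.allclose(f.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PFM columns must be non-negative and sum to 1")

    @property
    def length(self) -> int:
        return self.frequencies.shape[1]

    def reverse_complement(self) -> "PositionFrequencyMatrix":
        # complement = swap A<->T and C<->G rows; then reverse columns
        return PositionFrequencyMatrix(self.frequencies[::-1, ::-1].copy(),
                                       self.n_reads, self.pseudocount)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.frequencies.T, columns=list(BASE_ORDER))
        frame.insert(0, "position", np.arange(self.length))
        return frame


@dataclass(frozen=True)
class MatrixAlignment:
    """Placement of a PFM onto the intended target."""

    offset: int          # matrix column paired with target position 0
    strand: str          # "+" (forward) or "-" (reverse)
    score: float         # summed target-base frequency over the overlap


def filter_reads(reads: list[str], spec: SelexLibrarySpec
                 ) -> tuple[list[str], dict[str, int]]:
    """Keep reads with correct length and exact flank matches.

    Returns the extracted variable regions plus a tally of rejection reasons
    (``length`` before ``flank``); tally counts plus kept count equal the
    input count.
    """
    n5 = len(spec.flank5)
    kept: list[str] = []
    tally = {"length": 0, "flank": 0, "kept": 0}
    for read in reads:
        if len(read) != spec.read_length:
            tally["length"] += 1
            continue
        if not (read.startswith(spec.flank5) and read.endswith(spec.flank3)):
            tally["flank"] += 1
            continue
        kept.append(read[n5: n5 + spec.variable_length])
        tally["kept"] += 1
    return kept, tally


def sample_reads(filtered: list[str], n: int = 200, seed: int = 0) -> list[str]:
    """Uniform subsample without replacement, reproducible under ``seed``.

    Returns all reads (with a warning) when fewer than ``n`` are available.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not filtered:
        raise ValueError("no filtered reads to sample from")
    if len(filtered) <= n:
        if len(filtered) < n:
            warnings.warn(
                f"only {len(filtered)} filtered reads available; requested {n}",
                stacklevel=2,
            )
        return list(filtered)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(filtered), size=n, replace=False)
    return [filtered[i] for i in sorted(idx)]


def build_pfm(regions: list[str], pseudocount: float = 0.5
              ) -> PositionFrequencyMatrix:
    """Column-wise base frequencies with additive smoothing.

    ``frequency(b, i) = (count(b, i) + pseudocount) / (n + 4 * pseudocount)``.
    """
    if not regions:
        raise ValueError("no variable regions supplied")
    lengths = {len(r) for r in regions}
    if len(lengths) != 1:
        raise ValueError(f"mixed variable-region lengths: {sorted(lengths)}")
    L = lengths.pop()
    counts = np.zeros((4, L), dtype=float)
    for region in regions:
        for i, b in enumerate(region):
            counts[BASE_INDEX[b], i] += 1
    freqs = (counts + pseudocount) / (len(regions) + 4 * pseudocount)
    return PositionFrequencyMatrix(freqs, n_reads=len(regions),
                                   pseudocount=pseudocount)


def _alignment_score(pfm: PositionFrequencyMatrix, target: str, offset: int) -> float:
    return float(sum(pfm.frequencies[BASE_INDEX[b], offset + i]
                     for i, b in enumerate(target)))


def align_and_trim_pfm(pfm: PositionFrequencyMatrix, intended_target: str
                       ) -> tuple[MatrixAlignment, PositionFrequencyMatrix]:
    """Best placement of the matrix on the intended target, both strands.

    The score of (offset, strand) is the summed frequency of the target base
    at each overlapped column, with the target reverse-complemented on the
    reverse strand. All offsets and both strands are searched exhaustively;
    ties resolve to the forward strand, then the smallest offset. The matrix
    is trimmed to the ``len(target)`` columns under the best placement and,
    for reverse-strand hits, reported in target orientation.
    """
    L, T = pfm.length, len(intended_target)
    if L < T:
        raise ValueError(f"matrix length {L} shorter than target length {T}")
    target_rc = revcomp(intended_target)
    best: tuple[float, int, int] | None = None  # (score, strand_rank, offset)
    for strand_rank, tgt in enumerate((intended_target, target_rc)):
        for offset in range(L - T + 1):
            score = _alignment_score(pfm, tgt, offset)
            key = (-score, strand_rank, offset)
            if best is None or key < best:
                best = key
    score, strand_rank, offset = -best[0], best[1], best[2]
    strand = "+" if strand_rank == 0 else "-"
    trimmed = PositionFrequencyMatrix(
        pfm.frequencies[:, offset: offset + T].copy(), pfm.n_reads, pfm.pseudocount
    )
    if strand == "-":
        trimmed = trimmed.reverse_complement()
    return MatrixAlignment(offset=offset, strand=strand, score=score), trimmed


def orient_regions(regions: list[str], alignment: MatrixAlignment,
                   target_length: int) -> list[str]:
    """Project variable regions onto target coordinates per an alignment."""
    out = []
    for r in regions:
        window = r[alignment.offset: alignment.offset + target_length]
        out.append(revcomp(window) if alignment.strand == "-" else window)
    return out


def discrimination_at_positions(aligned_regions: list[str],
                                positions: list[tuple[int, str, str]]
                                ) -> pd.DataFrame:
    """Base percentages at discriminatory positions.

    ``positions`` lists (index in target coordinates, on-target base,
    off-target base). For each, the percentage of reads carrying the
    on-target base, the off-target base, and any other base is reported;
    the three percentages sum to 100.
    """
    if not aligned_regions:
        raise ValueError("no aligned reads supplied")
    n = len(aligned_regions)
    rows = []
    for index, on_base, off_base in positions:
        if not 0 <= index < len(aligned_regions[0]):
            raise ValueError(f"position {index} outside target")
        column = [r[index] for r in aligned_regions]
        n_on = sum(b == on_base for b in column)
        n_off = sum(b == off_base for b in column)
        rows.append({
            "position": index, "on_base": on_base, "off_base": off_base,
            "percent_on": 100.0 * n_on / n,
            "percent_off": 100.0 * n_off / n,
            "percent_other": 100.0 * (n - n_on - n_off) / n,
        })
    return pd.DataFrame(rows)


def pfm_to_meme(pfm: PositionFrequencyMatrix, name: str = "motif") -> str:
    """Minimal MEME-format record for one motif."""
    lines = [
        "MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pfm.length} "
        f"nsites= {pfm.n_reads} E= 0",
    ]
    for col in pfm.frequencies.T:
        lines.append(" " + " ".join(f"{x:.6f}" for x in col))
    return "\n".join(lines) + "\n"
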