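"""Amplicon indel calling and nuclease specificity statistics.

Reads from a deep-sequenced locus are globally aligned to the amplicon
reference with affine gap penalties (Gotoh algorithm; match +1, mismatch -2,
gap open -6, gap extend -1, deterministic traceback preferring diagonal,
then up, then left on ties). A read is scored indel-positive iff an
alignment gap overlaps the padded cut window. Treated-vs-control indel
counts are compared with a one-sided Fisher's exact test (hypergeometric
tail), Bonferroni-adjusted over the batch; activity, on:off specificity
ratios and aggregate off-target activity follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import hypergeom

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -2.0, -6.0, -1.0

_OP_MATCH, _OP_INS, _OP_DEL = 0, 1, 2  # ins consumes read, del consumes ref
_NEG = -1e18


@dataclass(frozen=True)
class AmpliconRef:
    """Reference amplicon for one locus with its expected cut interval."""

    name: str
    reference: str
    cut_start: int
    cut_end: int
    pad: int = 10  # bp added to each side of the cut interval when scoring

    def __post_init__(self) -> None:
        if not 0 <= self.cut_start <= self.cut_end <= len(self.reference):
            raise ValueError(f"cut interval outside reference for {self.name}")

    @property
    def window(self) -> tuple[int, int]:
        return (max(0, self.cut_start - self.pad),
                min(len(self.reference), self.cut_end + self.pad))


@njit(cache=True)
def _gotoh_kernel(read, ref, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n, m = read.shape[0], ref.shape[0]
    H = np.empty((n + 1, m + 1))
    E = np.empty((n + 1, m + 1))  # gap in read (consumes ref, "left")
    F = np.empty((n + 1, m + 1))  # gap in ref (consumes read, "up")
    H[0, 0], E[0, 0], F[0, 0] = 0.0, _NEG, _NEG
    for j in range(1, m + 1):
        E[0, j] = gap_open + (j - 1) * gap_ext
        H[0, j] = E[0, j]
        F[0, j] = _NEG
    for i in range(1, n + 1):
        F[i, 0] = gap_open + (i - 1) * gap_ext
        H[i, 0] = F[i, 0]
        E[i, 0] = _NEG
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_ext)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_ext)
            s = match if read[i - 1] == ref[j - 1] else mismatch
            H[i, j] = max(H[i - 1, j - 1] + s, F[i, j], E[i, j])
    # traceback: ties prefer diagonal, then up (F), then left (E)
    ops = np.empty(n + m, dtype=np.uint8)
    k = 0
    i, j = n, m
    state = 0  # 0 = H, 1 = F, 2 = E
    while i > 0 or j > 0:
        if state == 0:
            s = match if (i > 0 and j > 0 and read[i - 1] == ref[j - 1]) else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                ops[k] = _OP_MATCH
                k += 1
                i -= 1
                j -= 1
            elif i > 0 and H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            closing = H[i - 1, j] + gap_open >= F[i - 1, j] + gap_ext or i == 1
            ops[k] = _OP_INS
            k += 1
            i -= 1
            if closing:
                state = 0
        else:
            closing = H[i, j - 1] + gap_open >= E[i, j - 1] + gap_ext or j == 1
            ops[k] = _OP_DEL
            k += 1
            j -= 1
            if closing:
                state = 0
    return H[n, m], ops[:k][::-1].copy()


@dataclass(frozen=True)
class Gap:
    """One alignment gap in reference coordinates.

    Deletions (bases missing from the read) span ``[ref_start, ref_end)``;
    insertions (extra read bases) sit at the zero-width junction
    ``ref_start == ref_end``.
    """

    kind: str        # "deletion" or "insertion"
    ref_start: int
    ref_end: int
    length: int


@dataclass(frozen=True)
class Alignment:
    score: float
    ops: tuple[int, ...]     # per-column op codes (0 match, 1 ins, 2 del)
    gaps: tuple[Gap, ...]
    identity: float          # match fraction over non-gap columns


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int8)


def align_read(read: str, ref: AmpliconRef | str,
               scoring: tuple[float, float, float, float] = (
                   MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)) -> Alignment:
    """Global affine-gap alignment of one read against the reference."""
    ref_seq = ref.reference if isinstance(ref, AmpliconRef) else ref
    if not read:
        raise ValueError("empty read")
    match, mismatch, gap_open, gap_ext = scoring
    if read == ref_seq:  # fast path: exact read
        n = len(read)
        return Alignment(score=n * match, ops=tuple([_OP_MATCH] * n),
                         gaps=(), identity=1.0)
    score, ops = _gotoh_kernel(_encode(read), _encode(ref_seq),
                               match, mismatch, gap_open, gap_ext)
    gaps: list[Gap] = []
    i = j = 0
    n_cols = n_matched = 0
    read_b, ref_b = read.encode(), ref_seq.encode()
    k = 0
    ops_list = ops.tolist()
    while k < len(ops_list):
        op = ops_list[k]
        if op == _OP_MATCH:
            n_cols += 1
            n_matched += read_b[i] == ref_b[j]
            i += 1
            j += 1
            k += 1
        else:
            run = k
            while run < len(ops_list) and ops_list[run] == op:
                run += 1
            length = run - k
            if op == _OP_INS:
                gaps.append(Gap("insertion", j, j, length))
                i += length
            else:
                gaps.append(Gap("deletion", j, j + length, length))
                j += length
            k = run
    identity = n_matched / n_cols if n_cols else 0.0
    return Alignment(score=float(score), ops=tuple(ops_list),
                     gaps=tuple(gaps), identity=identity)


def gap_in_window(gap: Gap, window: tuple[int, int]) -> bool:
    """Does a gap overlap the half-open window? Zero-width insertions count
    when their junction lies inside or on either window edge."""
    ws, we = window
    if gap.kind == "insertion":
        return ws <= gap.ref_start <= we
    return gap.ref_start < we and gap.ref_end > ws


@dataclass(frozen=True)
class LocusCalls:
    calls: pd.DataFrame        # per-read: read index, indel flag, identity
    n_scored: int
    n_indel: int
    frequency_percent: float
    n_discarded: int


def call_indels_for_locus(reads: list[str], ref: AmpliconRef,
                          min_identity: float = 0.6) -> LocusCalls:
    """Score reads as indel-positive within the padded cut window.

    Reads whose non-gap alignment identity falls below ``min_identity`` are
    discarded (not scored). frequency = 100 * n_indel / n_scored.
    """
    window = ref.window
    rows = []
    n_discarded = 0
    for idx, read in enumerate(reads):
        if len(read) < 20:
            n_discarded += 1
            continue
        aln = align_read(read, ref)
        if aln.identity < min_identity:
            n_discarded += 1
            continue
        has_indel = any(gap_in_window(g, window) for g in aln.gaps)
        rows.append({"read_index": idx, "indel": has_indel,
                     "identity": aln.identity})
    if not rows:
        raise ValueError(f"no scorable reads at locus {ref.name}")
    calls = pd.DataFrame(rows)
    n_scored = len(calls)
    n_indel = int(calls["indel"].sum())
    return LocusCalls(calls=calls, n_scored=n_scored, n_indel=n_indel,
                      frequency_percent=100.0 * n_indel / n_scored,
                      n_discarded=n_discarded)


def fisher_greater(k1, n1, k2, n2):
    """Vectorized one-sided Fisher's exact p (upper hypergeometric tail).

    Arguments may be scalars or equal-shape integer arrays.
    """
    k1 = np.asarray(k1)
    return hypergeom.sf(k1 - 1, np.asarray(n1) + np.asarray(n2),
                        k1 + np.asarray(k2), np.asarray(n1))


def compare_to_control(treated: tuple[int, int], control: tuple[int, int]) -> float:
    """One-sided Fisher's exact test that the treated indel proportion
    exceeds the control's.

    With margins fixed, the p-value is the upper hypergeometric tail
    ``P(X >= k_treated)`` for ``X ~ Hypergeom(N, K, n_treated)`` where ``N``
    is the pooled read count and ``K`` the pooled indel count.
    """
    k1, n1 = treated
    k2, n2 = control
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("totals must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"indel count {k} outside [0, {n}]")
    return float(fisher_greater(k1, n1, k2, n2))


def adjust_bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni family-wise correction: ``min(1, m * p)``."""
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


@dataclass(frozen=True)
class LocusResult:
    """Per-locus modification outcome versus its cognate control."""

    name: str
    n_reads: int
    n_indel: int
    frequency_percent: float
    control_n_reads: int
    control_n_indel: int
    control_frequency_percent: float
    p_value: float
    adjusted_p: float = math.nan
    active: bool = False
    kind: str = "off"  # "on" or "off" target

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def locus_result(name: str, treated: LocusCalls, control: LocusCalls,
                 kind: str = "off") -> LocusResult:
    p = compare_to_control((treated.n_indel, treated.n_scored),
                           (control.n_indel, control.n_scored))
    return LocusResult(
        name=name, n_reads=treated.n_scored, n_indel=treated.n_indel,
        frequency_percent=treated.frequency_percent,
        control_n_reads=control.n_scored, control_n_indel=control.n_indel,
        control_frequency_percent=control.frequency_percent,
        p_value=p, kind=kind,
    )


@dataclass(frozen=True)
class RatioResult:
    """On:off specificity ratio, with a lower bound when off activity is 0."""

    ratio: float | None
    lower_bound: float | None = None
    undefined: bool = False

    @property
    def display(self) -> str:
        if self.undefined:
            return "undefined"
        if self.ratio is None:
            return f"> {self.lower_bound:g}"
        return f"{self.ratio:g}"


def specificity_ratio(on_percent: float, off_percent: float,
                      floor: float | None = None) -> RatioResult:
    """Ratio of on-target to off-target indel frequency.

    When the off-target frequency is exactly 0 the ratio is reported as a
    lower bound ``> on/floor`` against the batch background floor (e.g. the
    GFP-control frequency); 0/0 is undefined.
    """
    if on_percent < 0 or off_percent < 0:
        raise ValueError("frequencies must be non-negative")
    if off_percent > 0:
        return RatioResult(ratio=on_percent / off_percent)
    if on_percent == 0:
        return RatioResult(ratio=None, undefined=True)
    if floor is None or floor <= 0:
        return RatioResult(ratio=None, undefined=True)
    return RatioResult(ratio=None, lower_bound=on_percent / floor)


@dataclass(frozen=True)
class SpecificityReport:
    """Batch summary: active off-targets and aggregate off-target activity."""

    off_targets: tuple[LocusResult, ...]
    aggregate_percent: float
    n_active: int
    on_target: LocusResult | None = None
    fold_vs_comparator: int | None = None
    fold_lower_bound: float | None = None
    ratios: tuple[RatioResult, ...] = field(default_factory=tuple)


def aggregate_offtarget(results: list[LocusResult], alpha: float = 0.05,
                        comparator_aggregate: float | None = None,
                        floor: float = 0.1,
                        on_target: LocusResult | None = None
                        ) -> SpecificityReport:
    """Flag active loci, sum their activity and compare to a comparator.

    A locus is active iff its Bonferroni-adjusted p is below ``alpha`` AND
    its frequency exceeds the control frequency; the aggregate is the sum of
    active frequencies (percent). With a comparator aggregate, the fold
    decrease ``comparator / aggregate`` is reported rounded to the nearest
    integer, or as a lower bound ``>= comparator / floor`` when the measured
    aggregate is 0.
    """
    adjusted = adjust_bonferroni([r.p_value for r in results])
    flagged = []
    for r, adj in zip(results, adjusted):
        active = adj < alpha and r.frequency_percent > r.control_frequency_percent
        flagged.append(LocusResult(**{**r.to_dict(), "adjusted_p": adj,
                                      "active": active}))
    active_loci = [r for r in flagged if r.active]
    aggregate = float(sum(r.frequency_percent for r in active_loci))
    fold = fold_lb = None
    if comparator_aggregate is not None:
        if aggregate > 0:
            fold = round(comparator_aggregate / aggregate)
        else:
            fold_lb = comparator_aggregate / floor
    return SpecificityReport(off_targets=tuple(flagged),
                             aggregate_percent=aggregate,
                             n_active=len(active_loci), on_target=on_target,
                             fold_vs_comparator=fold, fold_lower_bound=fold_lb)
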