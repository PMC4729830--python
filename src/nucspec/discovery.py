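"""IDLV-capture off-target discovery.

Integration junctions tagged by an integrase-defective lentiviral vector mark
double-strand-break sites genome-wide. The discovery algorithm: map junction
segments (exact search on a desk-scale genome), collapse duplicate
coordinates per sample, merge integrations within 1 kb of each other into
clusters (single linkage), keep clusters present in at least two of three
treated replicates and at most one of three control replicates, rank by the
total number of unique integrations in treated samples, take the top 20, and
annotate each candidate with putative nuclease dimer binding sites (paired
half-sites on opposite strands separated by a short spacer).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .targets import revcomp

INTEGRATION_COLUMNS = ["chrom", "position", "strand", "sample", "replicate", "group"]


@dataclass(frozen=True)
class DimerSiteMatch:
    """A putative paired-half-site binding site within a cluster window."""

    chrom: str
    left_start: int
    left_strand: str
    left_mismatches: int
    right_start: int
    right_strand: str
    right_mismatches: int
    spacer: int
    orientation: str  # which half-site occupies the upstream position

    @property
    def total_mismatches(self) -> int:
        return self.left_mismatches + self.right_mismatches


@dataclass(frozen=True)
class Cluster:
    """A merged run of integrations: the unit of candidate off-target loci."""

    chrom: str
    start: int
    end: int  # half-open; single-integration clusters have width 1
    treated_counts: dict[int, int] = field(default_factory=dict)
    control_counts: dict[int, int] = field(default_factory=dict)
    rank: int | None = None
    drop_reason: str | None = None
    annotations: tuple[DimerSiteMatch, ...] = ()

    @property
    def n_treated_replicates_present(self) -> int:
        return sum(1 for v in self.treated_counts.values() if v > 0)

    @property
    def n_control_replicates_present(self) -> int:
        return sum(1 for v in self.control_counts.values() if v > 0)

    @property
    def total_unique_treated(self) -> int:
        return sum(self.treated_counts.values())

    @property
    def total_unique_control(self) -> int:
        return sum(self.control_counts.values())

    @property
    def treated_control_ratio(self) -> float:
        ctrl = self.total_unique_control
        return float("inf") if ctrl == 0 else self.total_unique_treated / ctrl

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def map_junctions_exact(junction_reads: list[tuple[str, str]],
                        genome: dict[str, str]
                        ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Locate genomic junction segments by exact search over both strands.

    ``junction_reads`` are (name, segment) pairs where the name encodes
    ``sample:replicate:group``. A segment placing uniquely (one hit across
    both strands of all chromosomes) yields one integration at its
    junction-side coordinate: the segment start for forward hits, reported on
    the forward axis with strand "-" for reverse-complement hits. Reads with
    zero or multiple hits are discarded and tallied.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    rows = []
    tally = {"mapped": 0, "unmapped": 0, "ambiguous": 0}
    for name, segment in junction_reads:
        hits: list[tuple[str, int, str]] = []
        for query, strand in ((segment, "+"), (revcomp(segment), "-")):
            for chrom, seq in genome.items():
                start = seq.find(query)
                while start != -1:
                    hits.append((chrom, start, strand))
                    if len(hits) > 1:
                        break
                    start = seq.find(query, start + 1)
                if len(hits) > 1:
                    break
            if len(hits) > 1:
                break
        if len(hits) == 0:
            tally["unmapped"] += 1
            continue
        if len(hits) > 1:
            tally["ambiguous"] += 1
            continue
        chrom, start, strand = hits[0]
        sample, replicate, group = name.split(":")[:3]
        position = start if strand == "+" else start + len(segment) - 1
        rows.append({"chrom": chrom, "position": position, "strand": strand,
                     "sample": sample, "replicate": int(replicate),
                     "group": group})
        tally["mapped"] += 1
    return pd.DataFrame(rows, columns=INTEGRATION_COLUMNS), tally


def dedupe_integrations(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse records identical in (chrom, position, strand, sample).

    The same coordinate seen in different samples/replicates stays distinct.
    Multiplicity is retained in a ``multiplicity`` column.
    """
    if table.empty:
        out = table.copy()
        out["multiplicity"] = pd.Series(dtype=int)
        return out
    keys = ["chrom", "position", "strand", "sample"]
    carried = [c for c in table.columns if c not in keys]
    grouped = table.groupby(keys, as_index=False, sort=True).agg(
        multiplicity=("position", "size"),
        **{c: (c, "first") for c in carried},
    )
    return grouped[keys + carried + ["multiplicity"]]


def merge_clusters(table: pd.DataFrame, distance: int = 1000) -> list[Cluster]:
    """Single-linkage merge of integrations within ``distance`` bp.

    Two integrations land in one cluster iff they are connected by a chain
    of same-chromosome gaps each ``<= distance``; strand is ignored. Input
    is sorted internally. Counts are unique integrations per replicate and
    group.
    """
    if distance <= 0:
        raise ValueError("merge distance must be positive")
    clusters: list[Cluster] = []
    if table.empty:
        return clusters
    frame = table.sort_values(["chrom", "position"], kind="mergesort")
    for chrom, sub in frame.groupby("chrom", sort=True):
        positions = sub["position"].to_numpy()
        breaks = np.nonzero(np.diff(positions) > distance)[0] + 1
        for block in np.split(np.arange(len(sub)), breaks):
            members = sub.iloc[block]
            treated: dict[int, int] = {}
            control: dict[int, int] = {}
            for (group, rep), cnt in members.groupby(
                    ["group", "replicate"], sort=True).size().items():
                (treated if group == "treated" else control)[int(rep)] = int(cnt)
            start = int(members["position"].min())
            end = int(members["position"].max()) + 1
            clusters.append(Cluster(chrom=str(chrom), start=start, end=end,
                                    treated_counts=treated,
                                    control_counts=control))
    return clusters


def filter_clusters(clusters: list[Cluster], min_treated_reps: int = 2,
                    max_control_reps: int = 1
                    ) -> tuple[list[Cluster], list[Cluster]]:
    """Replicate-presence filter separating candidates from dropped clusters.

    Retains clusters with integrations in at least ``min_treated_reps``
    treated replicates and at most ``max_control_reps`` control replicates;
    every dropped cluster carries a machine-readable reason.
    """
    kept, dropped = [], []
    for c in clusters:
        reasons = []
        if c.n_treated_replicates_present < min_treated_reps:
            reasons.append(
                f"treated_replicates={c.n_treated_replicates_present}"
                f"<{min_treated_reps}")
        if c.n_control_replicates_present > max_control_reps:
            reasons.append(
                f"control_replicates={c.n_control_replicates_present}"
                f">{max_control_reps}")
        if reasons:
            dropped.append(replace(c, drop_reason=";".join(reasons)))
        else:
            kept.append(c)
    return kept, dropped


def rank_clusters(candidates: list[Cluster], top_n: int = 20) -> list[Cluster]:
    """Deterministic total order over candidates; top N returned ranked 1..N.

    Primary key: total unique treated integrations (descending). Ties break
    by number of treated replicates present (descending), then the
    treated:control count ratio (descending, zero-control counted as
    infinite), then (chromosome, start) ascending.
    """
    def key(c: Cluster):
        return (-c.total_unique_treated, -c.n_treated_replicates_present,
                -c.treated_control_ratio, c.chrom, c.start)

    ordered = sorted(candidates, key=key)[:top_n]
    return [replace(c, rank=i + 1) for i, c in enumerate(ordered)]


def _hamming_profile(window: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` at every start position of ``window``."""
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    k, n = len(pat), len(window)
    if n < k:
        return np.empty(0, dtype=int)
    strided = np.lib.stride_tricks.sliding_window_view(window, k)
    return (strided != pat).sum(axis=1)


def scan_dimer_sites(chrom: str, start: int, end: int, genome: dict[str, str],
                     left_target: str, right_target: str,
                     spacer_range: tuple[int, int] = (4, 7),
                     max_mismatches: int = 3,
                     flank: int = 250) -> list[DimerSiteMatch]:
    """Exhaustive paired-half-site scan around a cluster span.

    Searches the window ``[start - flank, end + flank)`` for one half-site on
    the plus strand followed, after a spacer of ``spacer_range`` bp, by the
    other half-site on the minus strand — in both half-site orders. A match
    requires at most ``max_mismatches`` Hamming mismatches per half-site.
    Results are sorted by total mismatches, then coordinate.
    """
    lo, hi = spacer_range
    if hi < lo:
        raise ValueError("empty spacer range")
    seq = genome[chrom]
    w_start = max(0, start - flank)
    w_end = min(len(seq), end + flank)
    window = np.frombuffer(seq[w_start:w_end].encode(), dtype=np.uint8)
    halves = {"left": left_target, "right": right_target}
    # profile[name][s] = mismatches of the plus-strand pattern at window pos s
    profiles = {
        (name, strand): _hamming_profile(
            window, half if strand == "+" else revcomp(half))
        for name, half in halves.items() for strand in "+-"
    }
    matches: list[DimerSiteMatch] = []
    for first, second in (("left", "right"), ("right", "left")):
        len1, len2 = len(halves[first]), len(halves[second])
        prof1 = profiles[(first, "+")]
        prof2 = profiles[(second, "-")]
        for spacer in range(lo, hi + 1):
            shift = len1 + spacer
            n = min(len(prof1), len(prof2) - shift if len(prof2) > shift else 0)
            if n <= 0:
                continue
            mm1 = prof1[:n]
            mm2 = prof2[shift: shift + n]
            ok = np.nonzero((mm1 <= max_mismatches) & (mm2 <= max_mismatches))[0]
            for s in ok:
                pos1 = w_start + int(s)
                pos2 = pos1 + shift
                kwargs = {
                    f"{first}_start": pos1, f"{first}_strand": "+",
                    f"{first}_mismatches": int(mm1[s]),
                    f"{second}_start": pos2, f"{second}_strand": "-",
                    f"{second}_mismatches": int(mm2[s]),
                }
                matches.append(DimerSiteMatch(chrom=chrom, spacer=spacer,
                                              orientation=f"{first}-{second}",
                                              **kwargs))
    matches.sort(key=lambda m: (m.total_mismatches, m.left_start,
                                m.right_start, m.spacer, m.orientation))
    return matches


@dataclass(frozen=True)
class DiscoveryConfig:
    """Parameters of the discovery pipeline (defaults mirror the assay)."""

    merge_distance: int = 1000
    min_treated_reps: int = 2
    max_control_reps: int = 1
    top_n: int = 20
    spacer_range: tuple[int, int] = (4, 7)
    max_mismatches: int = 3
    scan_flank: int = 250


@dataclass(frozen=True)
class DiscoveryResult:
    candidates: list[Cluster]
    dropped: list[Cluster]
    n_unique_integrations: int


def discover(table: pd.DataFrame, config: DiscoveryConfig = DiscoveryConfig(),
             genome: dict[str, str] | None = None,
             left_target: str | None = None,
             right_target: str | None = None) -> DiscoveryResult:
    """End-to-end discovery: dedupe -> merge -> filter -> rank -> annotate.

    ``table`` holds integration records (see INTEGRATION_COLUMNS); pass a
    genome plus half-site targets to annotate candidates with putative dimer
    binding sites.
    """
    unique = dedupe_integrations(table)
    clusters = merge_clusters(unique, distance=config.merge_distance)
    kept, dropped = filter_clusters(clusters, config.min_treated_reps,
                                    config.max_control_reps)
    ranked = rank_clusters(kept, top_n=config.top_n)
    if genome is not None and left_target and right_target:
        ranked = [
            replace(c, annotations=tuple(scan_dimer_sites(
                c.chrom, c.start, c.end, genome, left_target, right_target,
                config.spacer_range, config.max_mismatches, config.scan_flank)))
            for c in ranked
        ]
    return DiscoveryResult(candidates=ranked, dropped=dropped,
                           n_unique_integrations=len(unique))


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Tabular view of clusters for TSV export."""
    rows = []
    for c in clusters:
        ann = c.annotations[0] if c.annotations else None
        rows.append({
            "rank": c.rank, "chrom": c.chrom, "start": c.start, "end": c.end,
            "total_unique_treated": c.total_unique_treated,
            "total_unique_control": c.total_unique_control,
            "n_treated_replicates": c.n_treated_replicates_present,
            "n_control_replicates": c.n_control_replicates_present,
            "treated_control_ratio": c.treated_control_ratio,
            "drop_reason": c.drop_reason or "",
            "n_dimer_site_matches": len(c.annotations),
            "best_site_mismatches": ann.total_mismatches if ann else None,
        })
    return pd.DataFrame(rows)
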