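"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the four experimental designs the pipeline consumes:

* IDLV-capture integration coordinates — treated replicates receive a
  Poisson-distributed number of integrations concentrated around each planted
  cut site (signed-geometric offsets) on top of a uniform genomic background;
  control replicates receive background only.
* Deep-sequenced amplicon reads — each read is the locus reference carrying,
  with the planted modification probability, a single insertion or deletion
  anchored in the cut interval, plus per-base substitution noise.
* SELEX pools — fixed 5'/3' flanks around a variable core sampled column-wise
  from a generating base-probability matrix, with an optional contaminant
  fraction of malformed reads to exercise filtering.
* Two-channel (GFP/mCherry) fluorescence events — a mixture of bivariate
  log-normal populations, 20,000 events by default.

Every draw flows from ``SimConfig.seed`` through per-operation substreams, so
a fixed config reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))
_SALT_GENOME, _SALT_CAPTURE, _SALT_AMPLICON, _SALT_FACS, _SALT_SELEX = 11, 23, 37, 53, 71


@dataclass(frozen=True)
class PlantedSite:
    """A nuclease cut site written into the synthetic genome."""

    name: str
    chrom: str
    position: int            # 0-based start of the site sequence
    sequence: str            # exact dimer-site sequence written at position
    kind: str = "off"        # "on" or "off" target
    intensity: float = 5.0   # mean integrations per treated replicate
    indel_rate: float = 0.0  # true modification rate for validation reads

    @property
    def end(self) -> int:
        return self.position + len(self.sequence)

    @property
    def center(self) -> int:
        return self.position + len(self.sequence) // 2


@dataclass(frozen=True)
class AmpliconSpec:
    """Reference amplicon and lesion model for one locus."""

    reference: str
    cut_start: int
    cut_end: int
    indel_rate: float = 0.0
    # indel length distribution: {length: probability}
    indel_lengths: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.2, 3: 0.15, 4: 0.1, 5: 0.08,
                                 6: 0.05, 7: 0.04, 10: 0.03}
    )
    substitution_rate: float = 0.001

    def __post_init__(self) -> None:
        if not (0 <= self.cut_start <= self.cut_end <= len(self.reference)):
            raise ValueError("cut interval must lie inside the reference")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError(f"indel rate {self.indel_rate} outside [0, 1]")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution rate outside [0, 1]")
        if max(self.indel_lengths) >= len(self.reference):
            raise ValueError("indel length must be shorter than the amplicon")


@dataclass(frozen=True)
class SelexSimSpec:
    """Generating model for a SELEX pool between fixed flanks."""

    flank5: str
    flank3: str
    matrix: tuple[tuple[float, ...], ...]  # 4 x L, rows A/C/G/T, columns sum to 1
    contaminant_fraction: float = 0.0

    def __post_init__(self) -> None:
        for fl in (self.flank5, self.flank3):
            if not fl or any(b not in "ACGT" for b in fl):
                raise ValueError(f"flank contains non-ACGT characters: {fl!r}")
        mat = np.asarray(self.matrix, dtype=float)
        if mat.shape[0] != 4:
            raise ValueError("matrix must have 4 rows (A, C, G, T)")
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-6):
            raise ValueError("matrix columns must each sum to 1")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant fraction outside [0, 1]")

    @property
    def variable_length(self) -> int:
        return len(self.matrix[0])


@dataclass(frozen=True)
class FacsPopulation:
    """One log-normal component of the fluorescence mixture."""

    weight: float
    log_mean_gfp: float
    log_sd_gfp: float
    log_mean_mcherry: float
    log_sd_mcherry: float

    def __post_init__(self) -> None:
        if self.log_sd_gfp <= 0 or self.log_sd_mcherry <= 0:
            raise ValueError("log-sd must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults mirror the capture-screen design: biologic triplicates of
    treated and control samples, a 1-kb-scale clustering problem with
    integrations tightly concentrated (geometric scale 50 bp) around cut
    sites over a 10 per Mb per replicate uniform background.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 1
    planted_sites: tuple[PlantedSite, ...] = ()
    background_rate: float = 10.0          # integrations per Mb per replicate
    n_treated_replicates: int = 3
    n_control_replicates: int = 3
    capture_offset_scale: float = 50.0     # bp, geometric spread around cut center
    amplicon: AmpliconSpec | None = None
    selex: SelexSimSpec | None = None
    facs: tuple[FacsPopulation, ...] = ()

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")
        if self.n_treated_replicates < 1:
            raise ValueError("need at least one treated replicate")
        per_chrom = self.genome_length // max(self.n_chromosomes, 1)
        for site in self.planted_sites:
            if any(b not in "ACGT" for b in site.sequence):
                raise ValueError(f"site {site.name} sequence not ACGT")
            if site.intensity < 0:
                raise ValueError(f"site {site.name} has negative intensity")
            if site.position < 0 or site.end > per_chrom:
                raise ValueError(f"site {site.name} outside chromosome bounds")

    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chromosome_length(self) -> int:
        return self.genome_length // self.n_chromosomes


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, salt])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def make_genome_with_sites(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Random-base chromosomes with each planted site written in place.

    Returns the genome as ``{chrom: sequence}`` plus a registry table with
    columns (name, chrom, start, end, strand, kind) in 0-based half-open
    coordinates. Overlapping planted sites raise, naming the offending pair.
    """
    rng = _rng(config, _SALT_GENOME)
    length = config.chromosome_length()
    genome = {chrom: _random_bases(rng, length) for chrom in config.chromosome_names()}

    by_chrom: dict[str, list[PlantedSite]] = {}
    for site in config.planted_sites:
        if site.chrom not in genome:
            raise ValueError(f"site {site.name} on unknown chromosome {site.chrom}")
        by_chrom.setdefault(site.chrom, []).append(site)
    for chrom, sites in by_chrom.items():
        sites.sort(key=lambda s: s.position)
        for a, b in zip(sites, sites[1:]):
            if b.position < a.end:
                raise ValueError(f"planted sites overlap: {a.name} and {b.name}")
        seq = genome[chrom]
        for site in sites:
            seq = seq[: site.position] + site.sequence + seq[site.end:]
        genome[chrom] = seq

    registry = pd.DataFrame(
        [
            {"name": s.name, "chrom": s.chrom, "start": s.position, "end": s.end,
             "strand": "+", "kind": s.kind, "intensity": s.intensity,
             "indel_rate": s.indel_rate}
            for s in config.planted_sites
        ],
        columns=["name", "chrom", "start", "end", "strand", "kind",
                 "intensity", "indel_rate"],
    )
    return genome, registry


def simulate_integration_replicates(config: SimConfig,
                                    registry: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate IDLV integration coordinates with truth labels.

    Treated replicates draw Poisson(intensity) integrations per planted site
    at ``site_center + sign * Geometric(1 / capture_offset_scale)``; every
    replicate (treated and control) additionally receives a uniform background
    at ``background_rate`` integrations per Mb. The ``origin`` column carries
    the planted-site name or ``"background"``.
    """
    rng = _rng(config, _SALT_CAPTURE)
    length = config.chromosome_length()
    rows: list[dict] = []
    groups = [("treated", config.n_treated_replicates),
              ("control", config.n_control_replicates)]
    p_geom = min(1.0, 1.0 / config.capture_offset_scale)
    centers = {
        r["name"]: (r["chrom"], (int(r["start"]) + int(r["end"])) // 2,
                    float(r["intensity"]))
        for r in registry.to_dict("records")
    }
    for group, n_reps in groups:
        for rep in range(1, n_reps + 1):
            sample = f"{group}{rep}"
            if group == "treated":
                for name, (chrom, center, intensity) in centers.items():
                    for _ in range(rng.poisson(intensity)):
                        offset = int(rng.geometric(p_geom)) * (1 if rng.random() < 0.5 else -1)
                        pos = int(np.clip(center + offset, 0, length - 1))
                        strand = "+" if rng.random() < 0.5 else "-"
                        rows.append({"chrom": chrom, "position": pos, "strand": strand,
                                     "sample": sample, "replicate": rep,
                                     "group": group, "origin": name})
            mean_bg = config.background_rate * length / 1e6
            for chrom in config.chromosome_names():
                for pos in rng.integers(0, length, size=rng.poisson(mean_bg)):
                    strand = "+" if rng.random() < 0.5 else "-"
                    rows.append({"chrom": chrom, "position": int(pos), "strand": strand,
                                 "sample": sample, "replicate": rep,
                                 "group": group, "origin": "background"})
    table = pd.DataFrame(
        rows, columns=["chrom", "position", "strand", "sample",
                       "replicate", "group", "origin"]
    )
    return table.sort_values(
        ["chrom", "position", "sample"], kind="mergesort"
    ).reset_index(drop=True)


def simulate_amplicon_reads(config: SimConfig, n_reads: int = 5000,
                            spec: AmpliconSpec | None = None,
                            salt: int = 0) -> pd.DataFrame:
    """Amplicon reads with per-read indel truth labels.

    Each read starts as the reference; with probability ``indel_rate`` a
    single insertion or deletion (length drawn from ``indel_lengths``) is
    anchored at a uniform position inside the cut interval, then per-base
    substitution noise is applied. Columns: read, true_indel, indel_kind,
    indel_length.
    """
    spec = spec if spec is not None else config.amplicon
    if spec is None:
        raise ValueError("no amplicon spec provided")
    rng = _rng(config, _SALT_AMPLICON + salt)
    ref = spec.reference
    lengths = np.array(sorted(spec.indel_lengths))
    probs = np.array([spec.indel_lengths[k] for k in lengths], dtype=float)
    probs = probs / probs.sum()

    rows = []
    for _ in range(n_reads):
        seq = ref
        kind, ln = "none", 0
        if rng.random() < spec.indel_rate:
            ln = int(rng.choice(lengths, p=probs))
            anchor = int(rng.integers(spec.cut_start, spec.cut_end + 1))
            if rng.random() < 0.5 and anchor + ln <= len(seq):
                kind = "deletion"
                seq = seq[:anchor] + seq[anchor + ln:]
            else:
                kind = "insertion"
                seq = seq[:anchor] + _random_bases(rng, ln) + seq[anchor:]
        if spec.substitution_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hit = np.nonzero(rng.random(len(arr)) < spec.substitution_rate)[0]
            for i in hit:
                choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
                arr[i] = bytes([choices[rng.integers(0, 3)]])
            seq = arr.tobytes().decode()
        rows.append({"read": seq, "true_indel": kind != "none",
                     "indel_kind": kind, "indel_length": ln})
    return pd.DataFrame(rows, columns=["read", "true_indel", "indel_kind", "indel_length"])


def simulate_facs_events(config: SimConfig, n_events: int = 20_000,
                         sample: str = "sample") -> pd.DataFrame:
    """Two-channel fluorescence events from a log-normal mixture.

    The default of 20,000 events mirrors the standard acquisition floor for
    mean-fluorescence estimation. Returns columns (sample, gfp, mcherry,
    population) with the generating component retained as truth.
    """
    if not config.facs:
        raise ValueError("config.facs defines no populations")
    weights = np.array([p.weight for p in config.facs], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError("population weights must sum to 1")
    rng = _rng(config, _SALT_FACS)
    which = rng.choice(len(weights), size=n_events, p=weights)
    gfp = np.empty(n_events)
    mch = np.empty(n_events)
    for k, pop in enumerate(config.facs):
        mask = which == k
        m = int(mask.sum())
        gfp[mask] = rng.lognormal(pop.log_mean_gfp, pop.log_sd_gfp, size=m)
        mch[mask] = rng.lognormal(pop.log_mean_mcherry, pop.log_sd_mcherry, size=m)
    return pd.DataFrame({"sample": sample, "gfp": gfp, "mcherry": mch,
                         "population": which})


def simulate_selex_reads(config: SimConfig, n_reads: int = 2000) -> pd.DataFrame:
    """SELEX pool reads: flank5 + matrix-sampled core + flank3.

    A ``contaminant_fraction`` of reads is deliberately malformed — truncated
    by one base or carrying a mutated flank base — to exercise the exact-match
    filter. Columns: read, contaminant.
    """
    spec = config.selex
    if spec is None:
        raise ValueError("no SELEX spec in config")
    rng = _rng(config, _SALT_SELEX)
    mat = np.asarray(spec.matrix, dtype=float)
    mat = mat / mat.sum(axis=0, keepdims=True)
    L = spec.variable_length
    cores = np.empty((n_reads, L), dtype="U1")
    for j in range(L):
        cores[:, j] = rng.choice(BASES, size=n_reads, p=mat[:, j])
    contam = rng.random(n_reads) < spec.contaminant_fraction
    rows = []
    for i in range(n_reads):
        core = "".join(cores[i])
        read = spec.flank5 + core + spec.flank3
        if contam[i]:
            if rng.random() < 0.5:
                read = read[:-1]  # wrong length
            else:               # mutate one flank base
                j = int(rng.integers(0, len(spec.flank5)))
                old = read[j]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                read = read[:j] + new + read[j + 1:]
        rows.append({"read": read, "contaminant": bool(contam[i])})
    return pd.DataFrame(rows, columns=["read", "contaminant"])


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different master seed."""
    return replace(config, seed=seed)
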