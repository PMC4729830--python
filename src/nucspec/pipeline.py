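"""Configuration and end-to-end orchestration.

``parse_config`` reads a declarative YAML config (nested sections, unknown
keys rejected, defaults materialized). ``run_full`` executes the
discovery-then-validation workflow on a synthetic experiment: generate a
genome with planted nuclease cut sites, simulate IDLV-capture integrations,
discover and rank candidate clusters, then validate every candidate by
simulated amplicon deep sequencing with treated-vs-control Fisher tests,
Bonferroni correction over the candidate batch, and a final specificity
report (active off-targets, aggregate off-target activity, fold change
versus a comparator aggregate). All intermediates are written with a
manifest carrying the config hash and seed, so a fixed config reproduces a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .amplicon import (AmpliconRef, LocusResult, aggregate_offtarget,
                       call_indels_for_locus, locus_result, specificity_ratio)
from .discovery import (Cluster, DiscoveryConfig, clusters_to_frame, discover)
from .synthetic_data import (AmpliconSpec, PlantedSite, SimConfig,
                             make_genome_with_sites, simulate_amplicon_reads,
                             simulate_integration_replicates)
from .targets import CCR5_RIGHT_TARGET, revcomp


@dataclass(frozen=True)
class SiteConfig:
    """One planted cut site; ``mismatches`` half-site bases are mutated."""

    name: str
    chrom: str = "chr1"
    position: int = 500_000
    kind: str = "off"
    intensity: float = 5.0
    indel_rate: float = 0.0
    mismatches: int = 0


@dataclass(frozen=True)
class TargetsConfig:
    """Half-site targets of the nuclease dimer under study."""

    left: str = "TGACCAGGCTAG"  # synthetic left half-site (supplementary-only in print)
    right: str = CCR5_RIGHT_TARGET
    spacer: int = 5


@dataclass(frozen=True)
class GenomeConfig:
    length: int = 2_000_000
    n_chromosomes: int = 2


@dataclass(frozen=True)
class CaptureConfig:
    background_rate: float = 10.0
    n_treated_replicates: int = 3
    n_control_replicates: int = 3
    offset_scale: float = 50.0


@dataclass(frozen=True)
class ClustersConfig:
    distance: int = 1000
    min_treated: int = 2
    max_control: int = 1
    top_n: int = 20


@dataclass(frozen=True)
class DimerScanConfig:
    spacer_min: int = 4
    spacer_max: int = 7
    max_mismatches: int = 3
    flank: int = 250


@dataclass(frozen=True)
class ValidationConfig:
    n_reads: int = 5000
    amplicon_length: int = 200
    substitution_rate: float = 0.001
    control_indel_rate: float = 0.001
    alpha: float = 0.05
    pad: int = 10
    comparator_aggregate: float | None = None
    floor: float = 0.1


@dataclass(frozen=True)
class GatesConfig:
    percentile: float = 0.995


@dataclass(frozen=True)
class SelexConfig:
    pseudocount: float = 0.5
    sample_n: int = 200


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/run"
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    capture: CaptureConfig = field(default_factory=CaptureConfig)
    targets: TargetsConfig = field(default_factory=TargetsConfig)
    sites: tuple[SiteConfig, ...] = ()
    clusters: ClustersConfig = field(default_factory=ClustersConfig)
    dimer_scan: DimerScanConfig = field(default_factory=DimerScanConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    gates: GatesConfig = field(default_factory=GatesConfig)
    selex: SelexConfig = field(default_factory=SelexConfig)


_SECTION_TYPES = {
    "genome": GenomeConfig, "capture": CaptureConfig, "targets": TargetsConfig,
    "clusters": ClustersConfig, "dimer_scan": DimerScanConfig,
    "validation": ValidationConfig, "gates": GatesConfig, "selex": SelexConfig,
}


def _build_section(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown keys in {context}: {', '.join(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(data) - top_known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    kwargs: dict = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value or {}, key)
        elif key == "sites":
            kwargs[key] = tuple(
                _build_section(SiteConfig, s, f"sites[{i}]")
                for i, s in enumerate(value or [])
            )
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def parse_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline config, materializing defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def config_to_dict(config: PipelineConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config)))


def serialize_config(config: PipelineConfig) -> str:
    return yaml.safe_dump(config_to_dict(config), sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Hash of the study parameters (the output location is provenance-free)."""
    data = config_to_dict(config)
    data.pop("outdir", None)
    return hashlib.sha256(
        yaml.safe_dump(data, sort_keys=True).encode()).hexdigest()


def _site_sequence(site: SiteConfig, targets: TargetsConfig,
                   rng: np.random.Generator) -> str:
    """Dimer site: left half-site + spacer + reverse-complemented right.

    ``site.mismatches`` random half-site bases are substituted so off-target
    sites diverge from the intended target.
    """
    spacer = "".join(rng.choice(list("ACGT"), size=targets.spacer))
    seq = targets.left + spacer + revcomp(targets.right)
    half_positions = [i for i in range(len(seq))
                      if i < len(targets.left) or i >= len(seq) - len(targets.right)]
    positions = rng.choice(half_positions, size=site.mismatches, replace=False)
    out = list(seq)
    for i in positions:
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def build_sim_config(config: PipelineConfig) -> SimConfig:
    """Materialize the synthetic study conditions from a pipeline config."""
    rng = np.random.default_rng([config.seed, 97])
    planted = tuple(
        PlantedSite(name=s.name, chrom=s.chrom, position=s.position,
                    sequence=_site_sequence(s, config.targets, rng),
                    kind=s.kind, intensity=s.intensity, indel_rate=s.indel_rate)
        for s in config.sites
    )
    return SimConfig(
        seed=config.seed,
        genome_length=config.genome.length,
        n_chromosomes=config.genome.n_chromosomes,
        planted_sites=planted,
        background_rate=config.capture.background_rate,
        n_treated_replicates=config.capture.n_treated_replicates,
        n_control_replicates=config.capture.n_control_replicates,
        capture_offset_scale=config.capture.offset_scale,
    )


def _candidate_truth(cluster: Cluster, registry: pd.DataFrame,
                     margin: int = 1000) -> tuple[str, str, float]:
    """(locus name, kind, true indel rate) for a candidate cluster."""
    for row in registry.to_dict("records"):
        if row["chrom"] == cluster.chrom and not (
                cluster.end + margin <= row["start"]
                or row["end"] + margin <= cluster.start):
            return row["name"], row["kind"], float(row["indel_rate"])
    return f"{cluster.chrom}:{cluster.start}", "off", 0.0


def validate_candidates(candidates: list[Cluster], genome: dict[str, str],
                        registry: pd.DataFrame, config: PipelineConfig
                        ) -> list[LocusResult]:
    """Simulated amplicon deep sequencing at each candidate locus.

    Treated reads carry the locus's true modification rate (0 for spurious
    clusters); cognate control reads carry the background lesion rate. Each
    locus is scored with the indel caller and compared with a one-sided
    Fisher's exact test.
    """
    val = config.validation
    results = []
    for k, cluster in enumerate(candidates):
        name, kind, rate = _candidate_truth(cluster, registry)
        chrom_seq = genome[cluster.chrom]
        mid = (cluster.start + cluster.end) // 2
        half = val.amplicon_length // 2
        lo = int(np.clip(mid - half, 0, len(chrom_seq) - val.amplicon_length))
        reference = chrom_seq[lo: lo + val.amplicon_length]
        cut = mid - lo
        spec_kwargs = dict(
            reference=reference,
            cut_start=int(np.clip(cut - 2, 0, val.amplicon_length)),
            cut_end=int(np.clip(cut + 2, 0, val.amplicon_length)),
            substitution_rate=val.substitution_rate,
        )
        sim = SimConfig(seed=config.seed)
        treated_reads = simulate_amplicon_reads(
            sim, n_reads=val.n_reads, salt=1000 + 2 * k,
            spec=AmpliconSpec(indel_rate=rate, **spec_kwargs))
        control_reads = simulate_amplicon_reads(
            sim, n_reads=val.n_reads, salt=1001 + 2 * k,
            spec=AmpliconSpec(indel_rate=val.control_indel_rate, **spec_kwargs))
        ref = AmpliconRef(name=name, reference=reference,
                          cut_start=spec_kwargs["cut_start"],
                          cut_end=spec_kwargs["cut_end"], pad=val.pad)
        treated = call_indels_for_locus(treated_reads["read"].tolist(), ref)
        control = call_indels_for_locus(control_reads["read"].tolist(), ref)
        results.append(locus_result(name, treated, control, kind=kind))
    return results


@dataclass(frozen=True)
class ReportBundle:
    outdir: Path
    report: dict
    artifacts: tuple[str, ...]


def run_full(config: PipelineConfig) -> ReportBundle:
    """Discovery followed by validation; writes the full report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)

    sim = build_sim_config(config)
    genome, registry = make_genome_with_sites(sim)
    integrations = simulate_integration_replicates(sim, registry)

    disc_config = DiscoveryConfig(
        merge_distance=config.clusters.distance,
        min_treated_reps=config.clusters.min_treated,
        max_control_reps=config.clusters.max_control,
        top_n=config.clusters.top_n,
        spacer_range=(config.dimer_scan.spacer_min, config.dimer_scan.spacer_max),
        max_mismatches=config.dimer_scan.max_mismatches,
        scan_flank=config.dimer_scan.flank,
    )
    disc = discover(integrations[nio.INTEGRATION_COLUMNS], disc_config,
                    genome=genome, left_target=config.targets.left,
                    right_target=config.targets.right)

    results = validate_candidates(disc.candidates, genome, registry, config)
    on = next((r for r in results if r.kind == "on"), None)
    off = [r for r in results if r.kind != "on"]
    report_obj = aggregate_offtarget(
        off, alpha=config.validation.alpha,
        comparator_aggregate=config.validation.comparator_aggregate,
        floor=config.validation.floor, on_target=on)
    ratios = {}
    if on is not None:
        for r in report_obj.off_targets:
            ratios[r.name] = specificity_ratio(
                on.frequency_percent, r.frequency_percent,
                floor=config.validation.floor).display

    # write bundle
    artifacts: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        artifacts.append(path)
        return path

    _write("genome.fasta", lambda p: nio.write_fasta(p, genome))
    _write("site_registry.tsv", lambda p: nio.write_tsv(p, registry))
    _write("integrations.bed",
           lambda p: nio.write_integrations_bed(p, integrations))
    _write("integration_truth.tsv", lambda p: nio.write_tsv(p, integrations))
    _write("candidates.tsv",
           lambda p: nio.write_tsv(p, clusters_to_frame(disc.candidates)))
    _write("dropped_clusters.tsv",
           lambda p: nio.write_tsv(p, clusters_to_frame(disc.dropped)))
    locus_frame = pd.DataFrame([r.to_dict() for r in report_obj.off_targets]
                               + ([on.to_dict()] if on is not None else []))
    _write("locus_results.tsv", lambda p: nio.write_tsv(p, locus_frame))

    report = {
        "config_sha256": chash,
        "seed": config.seed,
        "n_unique_integrations": disc.n_unique_integrations,
        "n_candidates": len(disc.candidates),
        "n_active_offtargets": report_obj.n_active,
        "aggregate_offtarget_percent": report_obj.aggregate_percent,
        "fold_vs_comparator": report_obj.fold_vs_comparator,
        "fold_lower_bound": report_obj.fold_lower_bound,
        "on_target": on.to_dict() if on is not None else None,
        "on_off_ratios": ratios,
    }
    _write("report.json", lambda p: Path(p).write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n"))
    nio.write_manifest(outdir / "manifest.json", config_hash=chash,
                       seed=config.seed, artifacts=artifacts)
    artifacts.append(outdir / "manifest.json")
    return ReportBundle(outdir=outdir, report=report,
                        artifacts=tuple(str(p) for p in artifacts))
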