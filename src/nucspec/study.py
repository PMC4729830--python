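"""Canonical synthetic study conditions for the capture-screen benchmarks.

The planted-recovery experiment mirrors the capture-assay design: biologic
triplicates of treated and control samples, five planted cut sites receiving
a mean of five integrations per treated replicate, and a uniform background
of 10 integrations per Mb per replicate over a two-chromosome 16-Mb toy
genome (~960 background integrations per run, matching the ~1,000-scale
background of a screen).
"""

from __future__ import annotations

import pandas as pd

from .discovery import DiscoveryConfig, discover
from .synthetic_data import (PlantedSite, SimConfig,
                             simulate_integration_replicates)

SITE_SEQUENCE = "GATGAGGATGACACGTAAAACTGCAAAAG"  # arbitrary 29-bp dimer site


def capture_screen_config(seed: int, n_sites: int = 5,
                          intensity: float = 5.0,
                          background_rate: float = 10.0) -> SimConfig:
    """Study conditions for the planted off-target recovery benchmark."""
    sites = tuple(
        PlantedSite(name=f"site{i}", chrom=f"chr{1 + i % 2}",
                    position=1_000_000 + 1_500_000 * (i // 2),
                    sequence=SITE_SEQUENCE, kind="off", intensity=intensity)
        for i in range(n_sites)
    )
    return SimConfig(seed=seed, genome_length=16_000_000, n_chromosomes=2,
                     planted_sites=sites, background_rate=background_rate,
                     n_treated_replicates=3, n_control_replicates=3,
                     capture_offset_scale=50.0)


def site_registry(config: SimConfig) -> pd.DataFrame:
    """Registry table of the planted sites (no genome build needed)."""
    return pd.DataFrame(
        [{"name": s.name, "chrom": s.chrom, "start": s.position,
          "end": s.end, "strand": "+", "kind": s.kind,
          "intensity": s.intensity, "indel_rate": s.indel_rate}
         for s in config.planted_sites],
        columns=["name", "chrom", "start", "end", "strand", "kind",
                 "intensity", "indel_rate"],
    )


def recovered_sites(config: SimConfig,
                    discovery: DiscoveryConfig = DiscoveryConfig(),
                    margin: int = 1000) -> tuple[set[str], int]:
    """Names of planted sites overlapped by a discovery candidate.

    Returns (recovered site names, number of candidates).
    """
    registry = site_registry(config)
    table = simulate_integration_replicates(config, registry)
    result = discover(table[["chrom", "position", "strand", "sample",
                             "replicate", "group"]], discovery)
    hits: set[str] = set()
    for c in result.candidates:
        for row in registry.to_dict("records"):
            if row["chrom"] == c.chrom and not (
                    c.end + margin <= row["start"]
                    or row["end"] + margin <= c.start):
                hits.add(row["name"])
    return hits, len(result.candidates)


def planted_site_sensitivity(seeds: list[int], **config_kwargs) -> float:
    """Fraction of planted sites recovered among candidates over seeds."""
    found = total = 0
    for seed in seeds:
        config = capture_screen_config(seed, **config_kwargs)
        hits, _ = recovered_sites(config)
        found += len(hits & {s.name for s in config.planted_sites})
        total += len(config.planted_sites)
    return found / total
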