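#!/usr/bin/env python
"""Generate the synthetic study: genome with planted nuclease cut sites,
IDLV-capture integration replicates, a SELEX pool and FACS events.

Writes the shared inputs consumed by the downstream analysis steps to
results/01_simulation/ and prints what was planted.
"""

from pathlib import Path

import numpy as np

from nucspec import io as nio
from nucspec.pipeline import (GenomeConfig, PipelineConfig, SiteConfig,
                              build_sim_config, serialize_config)
from nucspec.synthetic_data import (FacsPopulation, SelexSimSpec,
                                    make_genome_with_sites,
                                    simulate_facs_events,
                                    simulate_integration_replicates,
                                    simulate_selex_reads)
from nucspec.targets import (CCR5_RIGHT_TARGET, SELEX_FLANK3, SELEX_FLANK5,
                             SELEX_VARIABLE_LENGTH)

OUT = Path("results/01_simulation")
SEED = 0

STUDY = PipelineConfig(
    seed=SEED, outdir=str(OUT),
    genome=GenomeConfig(length=2_000_000, n_chromosomes=2),
    sites=(
        SiteConfig(name="on_target", chrom="chr1", position=400_000,
                   kind="on", intensity=15.0, indel_rate=0.30),
        SiteConfig(name="off_ccr2_like", chrom="chr2", position=700_000,
                   kind="off", intensity=6.0, indel_rate=0.004, mismatches=1),
        SiteConfig(name="off_diverged", chrom="chr1", position=800_000,
                   kind="off", intensity=6.0, indel_rate=0.0, mismatches=2),
    ),
)


def discriminating_matrix(seed: int, offset: int = 5,
                          p_target: float = 0.85) -> tuple[tuple[float, ...], ...]:
    """Generating matrix: the 12-nt target embedded in the 22-nt core."""
    rng = np.random.default_rng(seed)
    idx = {b: i for i, b in enumerate("ACGT")}
    mat = np.full((4, SELEX_VARIABLE_LENGTH), 0.25)
    for i, b in enumerate(CCR5_RIGHT_TARGET):
        col = np.full(4, (1 - p_target) / 3)
        col[idx[b]] = p_target
        mat[:, offset + i] = col
    return tuple(map(tuple, mat))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "config.yaml").write_text(serialize_config(STUDY))

    sim = build_sim_config(STUDY)
    genome, registry = make_genome_with_sites(sim)
    integrations = simulate_integration_replicates(sim, registry)
    nio.write_fasta(OUT / "genome.fasta", genome)
    nio.write_tsv(OUT / "site_registry.tsv", registry)
    nio.write_integrations_bed(OUT / "integrations.bed", integrations)
    nio.write_tsv(OUT / "integration_truth.tsv", integrations)

    import dataclasses
    selex_sim = dataclasses.replace(sim, selex=SelexSimSpec(
        flank5=SELEX_FLANK5, flank3=SELEX_FLANK3,
        matrix=discriminating_matrix(SEED), contaminant_fraction=0.20))
    pool = simulate_selex_reads(selex_sim, n_reads=3000)
    nio.write_fastq(OUT / "selex_pool.fastq",
                    [(f"read{i}", s) for i, s in enumerate(pool["read"])])

    facs_sim = dataclasses.replace(sim, facs=(
        FacsPopulation(1.0, 4.0, 0.3, 4.0, 0.3),))
    events = simulate_facs_events(facs_sim, sample="negative_control")
    nio.write_tsv(OUT / "facs_negative_control.tsv", events)

    n_sites = len(registry)
    n_treated = (integrations["group"] == "treated").sum()
    n_site_tagged = (integrations["origin"] != "background").sum()
    print(f"planted {n_sites} cut sites on a "
          f"{sim.genome_length / 1e6:.0f}-Mb, {sim.n_chromosomes}-chromosome genome")
    print(f"simulated {len(integrations)} integrations "
          f"({n_treated} treated-group, {n_site_tagged} site-derived)")
    print(f"SELEX pool: {len(pool)} reads, "
          f"{pool['contaminant'].mean():.1%} contaminants")
    print(f"FACS negative control: {len(events)} events")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
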