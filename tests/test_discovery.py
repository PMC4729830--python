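"""IDLV-capture discovery: mapping, dedup, clustering, filter, rank, scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nucspec.discovery import (Cluster, DiscoveryConfig, dedupe_integrations,
                               discover, filter_clusters, map_junctions_exact,
                               merge_clusters, rank_clusters, scan_dimer_sites)
from nucspec.synthetic_data import (PlantedSite, SimConfig,
                                    make_genome_with_sites,
                                    simulate_integration_replicates)
from nucspec.targets import revcomp


def integration_frame(records):
    """records: (chrom, position, strand, sample, replicate, group)"""
    return pd.DataFrame(records, columns=["chrom", "position", "strand",
                                          "sample", "replicate", "group"])


class TestMapJunctions:
    def test_unique_segment_maps_to_planted_coordinate(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 10_000))}
        segment = genome["chr1"][5000:5025]
        table, tally = map_junctions_exact([("treated1:1:treated", segment)],
                                           genome)
        assert tally["mapped"] == 1
        assert table.iloc[0]["position"] == 5000
        assert table.iloc[0]["strand"] == "+"

    def test_duplicated_segment_discarded_as_ambiguous(self):
        genome = {"chr1": "AAAACCCCGGGGTTTTAAAACCCCGGGGTTTT"}
        _, tally = map_junctions_exact([("s:1:treated", "AAAACCCCGGGGTTTT")],
                                       genome)
        assert tally["ambiguous"] == 1

    def test_reverse_strand_matches_naive_scan_oracle(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 5000))}
        segment = revcomp(genome["chr1"][3000:3025])
        table, tally = map_junctions_exact([("s:1:treated", segment)], genome)
        assert tally["mapped"] == 1
        # naive oracle: scan every start position on both strands
        hits = [(i, "+") for i in range(5000 - 24)
                if genome["chr1"][i:i + 25] == segment]
        hits += [(i, "-") for i in range(5000 - 24)
                 if revcomp(genome["chr1"][i:i + 25]) == segment]
        assert len(hits) == 1
        pos, strand = hits[0]
        assert table.iloc[0]["strand"] == strand == "-"
        assert table.iloc[0]["position"] == pos + 25 - 1

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty genome"):
            map_junctions_exact([("s:1:treated", "ACGT")], {})


class TestDedupe:
    def test_copies_collapse_with_multiplicity(self):
        table = integration_frame(
            [("chr1", 100, "+", "t1", 1, "treated")] * 10)
        unique = dedupe_integrations(table)
        assert len(unique) == 1
        assert unique.iloc[0]["multiplicity"] == 10

    def test_same_coordinate_in_two_replicates_stays_distinct(self):
        table = integration_frame([
            ("chr1", 100, "+", "t1", 1, "treated"),
            ("chr1", 100, "+", "t2", 2, "treated"),
        ])
        assert len(dedupe_integrations(table)) == 2

    def test_empty_table_passes_through(self):
        assert dedupe_integrations(integration_frame([])).empty


def oracle_single_linkage(positions, distance):
    """Brute-force transitive closure over the pairwise-distance graph."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(positions)))
    for i, j in itertools.combinations(range(len(positions)), 2):
        if abs(positions[i] - positions[j]) <= distance:
            g.add_edge(i, j)
    comps = []
    for comp in nx.connected_components(g):
        members = sorted(positions[i] for i in comp)
        comps.append((members[0], members[-1] + 1, len(comp)))
    return sorted(comps)


class TestMergeClusters:
    def frame(self, positions):
        return integration_frame(
            [("chr1", p, "+", "t1", 1, "treated") for p in positions])

    def test_gap_below_and_above_cutoff(self):
        clusters = merge_clusters(self.frame([100, 900, 2500]), distance=1000)
        spans = sorted((c.start, c.end) for c in clusters)
        assert spans == [(100, 901), (2500, 2501)]

    def test_chain_merges_transitively(self):
        clusters = merge_clusters(self.frame([0, 900, 1800, 2700]), distance=1000)
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (0, 2701)

    def test_empty_input_gives_empty_list(self):
        assert merge_clusters(self.frame([]), 1000) == []

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            merge_clusters(self.frame([1]), 0)

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 60))
            positions = sorted(rng.integers(0, 50_000, size=n).tolist())
            distance = int(rng.integers(1, 3000))
            clusters = merge_clusters(self.frame(positions), distance)
            got = sorted((c.start, c.end, c.total_unique_treated)
                         for c in clusters)
            assert got == oracle_single_linkage(positions, distance)

    def test_cluster_count_non_increasing_in_distance(self, rng):
        positions = sorted(rng.integers(0, 100_000, size=80).tolist())
        counts = [len(merge_clusters(self.frame(positions), d))
                  for d in (10, 100, 1000, 10_000)]
        assert counts == sorted(counts, reverse=True)

    def test_counts_split_by_group_and_replicate(self):
        table = integration_frame([
            ("chr1", 100, "+", "t1", 1, "treated"),
            ("chr1", 150, "-", "t1", 1, "treated"),
            ("chr1", 200, "+", "t2", 2, "treated"),
            ("chr1", 250, "+", "c1", 1, "control"),
        ])
        (cluster,) = merge_clusters(table, 1000)
        assert cluster.treated_counts == {1: 2, 2: 1}
        assert cluster.control_counts == {1: 1}


def presence_cluster(treated_reps, control_reps):
    return Cluster(chrom="chr1", start=0, end=1,
                   treated_counts={r: 1 for r in treated_reps},
                   control_counts={r: 1 for r in control_reps})


class TestFilterClusters:
    def test_two_treated_no_control_retained(self):
        kept, _ = filter_clusters([presence_cluster({1, 2}, set())])
        assert len(kept) == 1

    def test_single_treated_replicate_dropped(self):
        kept, dropped = filter_clusters([presence_cluster({1}, set())])
        assert not kept and "treated_replicates=1<2" in dropped[0].drop_reason

    def test_two_control_replicates_dropped(self):
        kept, dropped = filter_clusters([presence_cluster({1, 2, 3}, {1, 2})])
        assert not kept and "control_replicates=2>1" in dropped[0].drop_reason

    def test_exhaustive_presence_patterns(self):
        # all 2^6 treated/control presence patterns against the stated rule
        for pattern in itertools.product([0, 1], repeat=6):
            treated = {i + 1 for i in range(3) if pattern[i]}
            control = {i + 1 for i in range(3) if pattern[3 + i]}
            kept, dropped = filter_clusters(
                [presence_cluster(treated, control)])
            expected = len(treated) >= 2 and len(control) <= 1
            assert bool(kept) == expected
            assert len(kept) + len(dropped) == 1

    def test_output_is_subset_of_input(self, rng):
        clusters = [presence_cluster(
            set(rng.choice([1, 2, 3], size=rng.integers(0, 4), replace=False)),
            set(rng.choice([1, 2, 3], size=rng.integers(0, 4), replace=False)))
            for _ in range(50)]
        kept, dropped = filter_clusters(clusters)
        assert len(kept) + len(dropped) == len(clusters)
        assert all(c.drop_reason for c in dropped)


def counted_cluster(total, reps=3, control=0, chrom="chr1", start=0):
    per_rep = [total // reps + (1 if i < total % reps else 0)
               for i in range(reps)]
    return Cluster(chrom=chrom, start=start, end=start + 1,
                   treated_counts={i + 1: c for i, c in enumerate(per_rep) if c},
                   control_counts={1: control} if control else {})


class TestRankClusters:
    def test_orders_by_total_unique_treated(self):
        ranked = rank_clusters([counted_cluster(12), counted_cluster(5),
                                counted_cluster(30)])
        assert [c.total_unique_treated for c in ranked] == [30, 12, 5]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_replicate_count_breaks_ties(self):
        a = counted_cluster(10, reps=3, start=100)
        b = counted_cluster(10, reps=2, start=0)
        ranked = rank_clusters([b, a])
        assert ranked[0].n_treated_replicates_present == 3

    def test_zero_control_ratio_ranks_before_finite(self):
        a = counted_cluster(10, control=1, start=0)
        b = counted_cluster(10, control=0, start=100)
        ranked = rank_clusters([a, b])
        assert ranked[0].total_unique_control == 0

    def test_top_n_truncates_to_20(self):
        clusters = [counted_cluster(i + 1, start=10 * i) for i in range(35)]
        ranked = rank_clusters(clusters, top_n=20)
        assert len(ranked) == 20
        assert ranked[0].total_unique_treated == 35

    def test_ordering_is_deterministic_total_order(self, rng):
        clusters = [counted_cluster(int(rng.integers(1, 6)),
                                    reps=int(rng.integers(1, 4)),
                                    control=int(rng.integers(0, 3)),
                                    start=int(rng.integers(0, 10_000)))
                    for _ in range(40)]
        first = rank_clusters(list(clusters), top_n=40)
        second = rank_clusters(list(reversed(clusters)), top_n=40)
        assert [(c.chrom, c.start) for c in first] == \
            [(c.chrom, c.start) for c in second]


LEFT, RIGHT = "GATGAGGATGAC", "AAACTGCAAAAG"


def oracle_dimer_scan(seq, offset, left, right, spacer_range, max_mm):
    """Naive O(window * |site|) scan over all positions/orders/spacers."""
    found = []
    for first, second in ((left, right), (right, left)):
        name1 = "left" if first is left else "right"
        for spacer in range(spacer_range[0], spacer_range[1] + 1):
            total = len(first) + spacer + len(second)
            for s in range(len(seq) - total + 1):
                mm1 = sum(a != b for a, b in zip(seq[s:s + len(first)], first))
                tail = seq[s + len(first) + spacer: s + total]
                mm2 = sum(a != b for a, b in zip(tail, revcomp(second)))
                if mm1 <= max_mm and mm2 <= max_mm:
                    found.append((offset + s, name1, spacer, mm1, mm2))
    return sorted(found)


class TestScanDimerSites:
    def build_genome(self, rng, planted, at=5000, n=10_000):
        seq = "".join(rng.choice(list("ACGT"), n))
        return {"chr1": seq[:at] + planted + seq[at + len(planted):]}

    def test_exact_planted_site_found_with_zero_mismatches(self, rng):
        site = LEFT + "ACGTA" + revcomp(RIGHT)
        genome = self.build_genome(rng, site)
        matches = scan_dimer_sites("chr1", 5000, 5001, genome, LEFT, RIGHT,
                                   spacer_range=(4, 7), max_mismatches=0)
        assert len(matches) == 1
        m = matches[0]
        assert (m.left_start, m.spacer, m.total_mismatches) == (5000, 5, 0)
        assert (m.left_strand, m.right_strand) == ("+", "-")

    def test_mismatched_half_site_reported_with_counts(self, rng):
        right_mut = "AAGCTGCATAAG"  # 2 substitutions vs RIGHT
        site = LEFT + "ACGTA" + revcomp(right_mut)
        genome = self.build_genome(rng, site)
        matches = scan_dimer_sites("chr1", 5000, 5001, genome, LEFT, RIGHT,
                                   spacer_range=(5, 5), max_mismatches=3)
        best = matches[0]
        assert (best.left_mismatches, best.right_mismatches) == (0, 2)

    def test_matches_naive_oracle_on_random_window(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 10_000))}
        matches = scan_dimer_sites("chr1", 250, 9750, genome, LEFT, RIGHT,
                                   spacer_range=(4, 7), max_mismatches=1,
                                   flank=250)
        got = sorted((m.left_start if m.orientation == "left-right"
                      else m.right_start,
                      m.orientation.split("-")[0], m.spacer,
                      m.left_mismatches if m.orientation == "left-right"
                      else m.right_mismatches,
                      m.right_mismatches if m.orientation == "left-right"
                      else m.left_mismatches) for m in matches)
        expected = oracle_dimer_scan(genome["chr1"], 0, LEFT, RIGHT, (4, 7), 1)
        assert got == expected

    def test_empty_spacer_range_rejected(self, rng):
        genome = {"chr1": "ACGT" * 100}
        with pytest.raises(ValueError, match="spacer"):
            scan_dimer_sites("chr1", 0, 10, genome, LEFT, RIGHT,
                             spacer_range=(7, 4))


class TestDiscoverEndToEnd:
    def planted_config(self, seed, n_sites=5, intensity=5.0, background=10.0,
                       on_target=None):
        sites = []
        if on_target is not None:
            sites.append(PlantedSite("on", "chr1", 100_000, "ACGTTGCAGGTCATC",
                                     kind="on", intensity=on_target))
        sites += [
            PlantedSite(f"off{i}", f"chr{1 + i % 2}",
                        200_000 + 150_000 * i, "GATCGGATATCCGGT",
                        kind="off", intensity=intensity)
            for i in range(n_sites)
        ]
        return SimConfig(seed=seed, genome_length=2_000_000, n_chromosomes=2,
                         planted_sites=tuple(sites), background_rate=background)

    def run(self, config):
        _, registry = make_genome_with_sites(config)
        table = simulate_integration_replicates(config, registry)
        result = discover(table[["chrom", "position", "strand", "sample",
                                 "replicate", "group"]])
        return registry, result

    def candidate_hits(self, registry, result, margin=1000):
        hits = set()
        for c in result.candidates:
            for row in registry.to_dict("records"):
                if row["chrom"] == c.chrom and not (
                        c.end + margin <= row["start"]
                        or row["end"] + margin <= c.start):
                    hits.add(row["name"])
        return hits

    def test_planted_sites_recovered_among_candidates(self):
        config = self.planted_config(seed=101)
        registry, result = self.run(config)
        hits = self.candidate_hits(registry, result)
        assert {f"off{i}" for i in range(5)} <= hits

    def test_background_only_rarely_yields_candidates(self):
        # At genome-scale density, coincidental cross-replicate clusters are
        # rare; the equivalent per-bp density on this 2-Mb toy is ~1/Mb
        # (spurious-cluster frequency scales as density^2 x genome size).
        passes = 0
        for seed in range(30):
            config = self.planted_config(seed=seed, n_sites=0, background=1.0)
            _, result = self.run(config)
            passes += len(result.candidates) == 0
        assert passes >= 0.95 * 30

    def test_on_target_with_triple_intensity_ranks_first(self):
        for seed in (1, 2, 3):
            config = self.planted_config(seed=seed, intensity=5.0,
                                         on_target=15.0)
            registry, result = self.run(config)
            top = result.candidates[0]
            on = registry[registry["name"] == "on"].iloc[0]
            assert top.chrom == on["chrom"]
            assert abs(top.start - on["start"]) < 2000
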