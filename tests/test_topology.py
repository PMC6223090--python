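"""Loop/TAD handling, target-gene assignment, and expression comparisons."""

import numpy as np
import pandas as pd
import pytest

from tfburden.genes import GeneTable
from tfburden.intervals import GenomicInterval
from tfburden.topology import (
    LoopSet,
    TADSet,
    contact_frequency,
    expression_by_mutation_group,
    group_sites_by_mutation_count,
    proximity_target_genes,
    topo_target_genes,
)


def loopset(rows):
    return LoopSet(pd.DataFrame(
        rows, columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]
    ))


def genetable(rows):
    return GeneTable(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "expression"]
    ))


class TestLoopSet:
    def test_unordered_pairs_deduplicated(self):
        loops = loopset([
            ("c", 0, 10, "c", 100, 110),
            ("c", 100, 110, "c", 0, 10),  # same pair reversed
            ("c", 0, 10, "c", 200, 210),
        ])
        assert len(loops) == 2

    def test_bedpe_round_trip(self, tmp_path):
        loops = loopset([("c", 0, 10, "c", 100, 110), ("c", 5, 15, "c", 300, 320)])
        p = tmp_path / "l.bedpe"
        loops.write_bedpe(p)
        back = LoopSet.read_bedpe(p)
        assert back.df[["start_a", "end_a", "start_b", "end_b"]].equals(
            loops.df[["start_a", "end_a", "start_b", "end_b"]]
        )


class TestContactFrequency:
    def test_counts_anchor_overlaps(self):
        site = GenomicInterval("c", 50, 60)
        loops = loopset([
            ("c", 55, 70, "c", 500, 510),
            ("c", 40, 52, "c", 600, 610),
            ("c", 58, 59, "c", 700, 710),
            ("c", 200, 210, "c", 800, 810),  # no overlap
        ])
        assert contact_frequency([site], loops)[0] == 3

    def test_loop_touching_both_anchors_counted_once(self):
        site = GenomicInterval("c", 50, 120)
        loops = loopset([("c", 55, 70, "c", 100, 110)])
        assert contact_frequency([site], loops)[0] == 1

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        sites = []
        for _ in range(100):
            s = int(rng.integers(0, 50_000))
            sites.append(GenomicInterval("c", s, s + int(rng.integers(10, 400))))
        rows = []
        for _ in range(100):
            a = int(rng.integers(0, 50_000))
            b = int(rng.integers(0, 50_000))
            rows.append(("c", a, a + int(rng.integers(10, 300)),
                         "c", b, b + int(rng.integers(10, 300))))
        loops = loopset(rows)
        got = contact_frequency(sites, loops)
        for i, site in enumerate(sites):
            n = 0
            for row in loops.df.itertuples(index=False):
                hit_a = row.start_a < site.end and site.start < row.end_a
                hit_b = row.start_b < site.end and site.start < row.end_b
                n += hit_a or hit_b
            assert got[i] == n


class TestTADSet:
    def test_overlapping_domains_rejected(self):
        with pytest.raises(ValueError):
            TADSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)])

    def test_containing_lookup(self):
        tads = TADSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 100, 200)])
        assert tads.containing("c", 0).start == 0
        assert tads.containing("c", 150).start == 100
        assert tads.containing("c", 250) is None
        assert tads.containing("x", 5) is None


class TestTopoTargets:
    def setup_locus(self):
        # site at [100, 200); TADs [0, 1000) and [1000, 2000)
        site = GenomicInterval("c", 100, 200, summit=150)
        tads = TADSet([GenomicInterval("c", 0, 1000), GenomicInterval("c", 1000, 2000)])
        genes = genetable([
            ("in_tad", "c", 500, 600, "+", 1.0),
            ("cross_tad", "c", 1500, 1600, "+", 1.0),
            ("no_loop", "c", 700, 800, "+", 1.0),
        ])
        return site, tads, genes

    def test_loop_to_gene_in_same_tad(self):
        site, tads, genes = self.setup_locus()
        loops = loopset([("c", 120, 180, "c", 550, 560)])
        assert topo_target_genes(site, loops, tads, genes) == {"in_tad"}

    def test_loop_across_tad_boundary_excluded(self):
        site, tads, genes = self.setup_locus()
        loops = loopset([("c", 120, 180, "c", 1550, 1560)])
        assert topo_target_genes(site, loops, tads, genes) == set()

    def test_site_outside_all_tads_empty(self):
        site, _, genes = self.setup_locus()
        tads = TADSet([GenomicInterval("c", 5000, 6000)])
        loops = loopset([("c", 120, 180, "c", 550, 560)])
        assert topo_target_genes(site, loops, tads, genes) == set()

    def test_matches_conjunction_oracle_on_random_locus(self):
        rng = np.random.default_rng(1)
        tads = TADSet([GenomicInterval("c", i * 1000, (i + 1) * 1000)
                       for i in range(10)])
        gene_rows = []
        for i in range(40):
            s = int(rng.integers(0, 9_900))
            gene_rows.append((f"g{i}", "c", s, s + 80, "+", 1.0))
        genes = genetable(gene_rows)
        loop_rows = []
        for _ in range(60):
            a = int(rng.integers(0, 9_900))
            b = int(rng.integers(0, 9_900))
            loop_rows.append(("c", a, a + 50, "c", b, b + 50))
        loops = loopset(loop_rows)
        for _ in range(20):
            s = int(rng.integers(0, 9_800))
            site = GenomicInterval("c", s, s + 100, summit=s + 50)
            got = topo_target_genes(site, loops, tads, genes)
            # oracle: brute-force conjunction
            tad = tads.containing("c", s + 49)
            expected = set()
            for lrow in loops.df.itertuples(index=False):
                ha = lrow.start_a < site.end and site.start < lrow.end_a
                hb = lrow.start_b < site.end and site.start < lrow.end_b
                if not (ha or hb):
                    continue
                distal = []
                if ha and not hb:
                    distal = [(lrow.start_b, lrow.end_b)]
                elif hb and not ha:
                    distal = [(lrow.start_a, lrow.end_a)]
                else:
                    distal = [(lrow.start_a, lrow.end_a), (lrow.start_b, lrow.end_b)]
                for ds, de in distal:
                    for grow in genes.df.itertuples(index=False):
                        if (grow.start < de and ds < grow.end and tad is not None
                                and grow.start < tad.end and tad.start < grow.end):
                            expected.add(grow.gene_id)
            assert got == expected

    def test_topo_targets_subset_of_same_tad_genes(self, small_world):
        world = small_world
        tads, genes, loops = world["tads"], world["genes"], world["loops"]
        for site in world["sites"][:50]:
            targets = topo_target_genes(site, loops, tads, genes)
            tad = tads.containing(site.chrom, site.effective_summit() - 1)
            for gid in targets:
                row = genes.row_by_id(gid)
                assert tad is not None
                assert row.start < tad.end and tad.start < row.end


class TestProximityTargets:
    def test_monotone_in_distance(self, small_world):
        genes = small_world["genes"]
        for site in small_world["sites"][:50]:
            g50 = proximity_target_genes(site, genes, 50_000)
            g100 = proximity_target_genes(site, genes, 100_000)
            assert g50 <= g100


class TestExpressionComparison:
    def make_world(self, shift, seed=0, n=400, n_genes=300):
        rng = np.random.default_rng(seed)
        span = 2500
        sites = [GenomicInterval("c", 500 + i * span, 900 + i * span,
                                 summit=700 + i * span) for i in range(n)]
        length = 500 + n * span + 10_000
        tads = TADSet([GenomicInterval("c", i * 200_000, (i + 1) * 200_000)
                       for i in range(length // 200_000 + 1)])
        mut_counts = rng.poisson(1.5, size=n)
        gene_rows = []
        for i in range(n_genes):
            s = int(rng.integers(0, length - 2_000))
            gene_rows.append((f"g{i}", "c", s, s + 1_500, "+",
                              float(rng.lognormal(2.0, 0.5))))
        genes_df = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start",
                                                    "end", "strand", "expression"])
        # loops: each site to one distal (> 60 kb) same-TAD gene when available
        loop_rows, shifted = [], set()
        for i, site in enumerate(sites):
            tad = tads.containing("c", site.summit - 1)
            sub = genes_df[(genes_df["start"] < tad.end) & (genes_df["end"] > tad.start)]
            dist = np.abs(sub["start"].to_numpy() - site.summit)
            sub = sub[dist > 60_000]
            if len(sub) == 0:
                continue
            g = sub.iloc[int(rng.integers(0, len(sub)))]
            loop_rows.append(("c", site.summit - 100, site.summit + 100,
                              "c", g["start"], g["end"]))
            if mut_counts[i] >= 3:
                shifted.add(g["gene_id"])
        genes_df.loc[genes_df["gene_id"].isin(shifted), "expression"] *= np.exp(shift)
        return sites, mut_counts, loopset(loop_rows), tads, genetable(genes_df.values.tolist())

    def test_null_shift_gives_flat_comparison(self):
        sites, counts, loops, tads, genes = self.make_world(shift=0.0, seed=3)
        comp = expression_by_mutation_group(
            sites, counts, loops, tads, genes, mode="topological",
            n_region_sample=40, n_region_reps=5, n_gene_sample=40, n_gene_reps=30,
            seed=1,
        )
        assert comp.p_between("0", "3+") > 0.01

    def test_planted_shift_detected_topologically_only(self):
        sites, counts, loops, tads, genes = self.make_world(shift=1.0, seed=4)
        kw = dict(n_region_sample=40, n_region_reps=5, n_gene_sample=40,
                  n_gene_reps=30, seed=2)
        topo = expression_by_mutation_group(sites, counts, loops, tads, genes,
                                            mode="topological", **kw)
        prox = expression_by_mutation_group(sites, counts, loops, tads, genes,
                                            mode="proximity_50kb", **kw)
        assert topo.p_between("0", "3+") < 0.01
        mean_0 = topo.group_means["0"].mean()
        mean_3 = topo.group_means["3+"].mean()
        assert mean_3 > mean_0
        assert prox.p_between("0", "3+") > topo.p_between("0", "3+")

    def test_identical_seed_reproduces_comparison(self):
        sites, counts, loops, tads, genes = self.make_world(shift=0.5, seed=5)
        kw = dict(n_region_sample=40, n_region_reps=3, n_gene_sample=40,
                  n_gene_reps=20, seed=11)
        a = expression_by_mutation_group(sites, counts, loops, tads, genes,
                                         mode="topological", **kw)
        b = expression_by_mutation_group(sites, counts, loops, tads, genes,
                                         mode="topological", **kw)
        for k in a.group_means:
            assert np.array_equal(a.group_means[k], b.group_means[k])
        assert a.pairwise.equals(b.pairwise)

    def test_single_gene_rep_is_an_error(self):
        sites, counts, loops, tads, genes = self.make_world(shift=0.5, seed=6)
        with pytest.raises(ValueError):
            expression_by_mutation_group(sites, counts, loops, tads, genes,
                                         n_region_sample=40, n_region_reps=2,
                                         n_gene_sample=40, n_gene_reps=1, seed=0)

    def test_small_group_is_an_error(self):
        sites, counts, loops, tads, genes = self.make_world(shift=0.5, seed=7)
        with pytest.raises(ValueError, match="fewer"):
            expression_by_mutation_group(sites, counts, loops, tads, genes,
                                         n_region_sample=10_000, n_region_reps=2,
                                         n_gene_sample=40, n_gene_reps=5, seed=0)

    def test_group_labels_partition_counts(self):
        groups = group_sites_by_mutation_count([0, 1, 2, 3, 7, 0])
        assert list(groups["0"]) == [0, 5]
        assert list(groups["3+"]) == [3, 4]
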