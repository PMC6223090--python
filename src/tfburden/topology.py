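"""Chromatin loops, TADs, and topological target-gene assignment.

A gene is a topological target of a site when it overlaps the distal anchor
of a loop whose proximal anchor overlaps the site AND the gene lies in the
same TAD as the site summit. The expression comparison groups sites by core
mutation count (0, 1, 2, ≥3), pools target genes over repeated region
samples, and contrasts repeatedly sampled mean expressions between groups;
a linear-proximity mode (genes within 50 or 100 kb of the summit) serves as
the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .intervals import GenomicInterval

LOOP_COLUMNS = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]


class LoopSet:
    """Paired-anchor chromatin interactions (BEDPE-style), deduplicated as
    unordered anchor pairs."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in LOOP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"LoopSet missing columns: {missing}")
        if "weight" not in df.columns:
            df = df.assign(weight=1.0)
        key = df.apply(
            lambda r: tuple(
                sorted(
                    [
                        (r.chrom_a, r.start_a, r.end_a),
                        (r.chrom_b, r.start_b, r.end_b),
                    ]
                )
            ),
            axis=1,
        )
        self.df = df.loc[~key.duplicated()].reset_index(drop=True)
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def read_bedpe(cls, path) -> "LoopSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, : min(df.shape[1], 7)]
        cols = LOOP_COLUMNS + (["weight"] if df.shape[1] > 6 else [])
        df.columns = cols
        return cls(df)

    def write_bedpe(self, path) -> None:
        self.df[LOOP_COLUMNS + ["weight"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def anchor_trees(self) -> dict[str, IntervalTree]:
        """chrom -> IntervalTree of anchors, payload (loop_index, anchor_side)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for i, row in enumerate(self.df.itertuples(index=False)):
                for side, (c, s, e) in enumerate(
                    [
                        (row.chrom_a, row.start_a, row.end_a),
                        (row.chrom_b, row.start_b, row.end_b),
                    ]
                ):
                    trees.setdefault(c, IntervalTree()).addi(s, e, (i, side))
            self._trees = trees
        return self._trees


class TADSet:
    """Non-overlapping topologically-associating-domain intervals."""

    def __init__(self, intervals):
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self.by_chrom = {}
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping TADs on {chrom}: [{a.start},{a.end}) and "
                        f"[{b.start},{b.end})"
                    )
            self.by_chrom[chrom] = ivs

    def containing(self, chrom: str, pos0: int) -> GenomicInterval | None:
        """TAD containing a 0-based position, or None."""
        ivs = self.by_chrom.get(chrom, [])
        starts = [iv.start for iv in ivs]
        i = np.searchsorted(starts, pos0, side="right") - 1
        if i >= 0 and ivs[i].start <= pos0 < ivs[i].end:
            return ivs[i]
        return None


def contact_frequency(sites, loops: LoopSet) -> np.ndarray:
    """Number of loops touching each site with >= 1 bp anchor overlap.

    A loop whose both anchors overlap the site is counted once.
    """
    trees = loops.anchor_trees()
    counts = np.zeros(len(sites), dtype=np.int64)
    for i, site in enumerate(sites):
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        hits = {payload[0] for _, _, payload in map(tuple, tree.overlap(site.start, site.end))}
        counts[i] = len(hits)
    return counts


def topo_target_genes(site, loops: LoopSet, tads: TADSet, genes) -> set[str]:
    """Genes overlapping the distal anchor of any loop from the site, within
    the same TAD as the site summit. Empty when the site is in no TAD."""
    summit0 = site.effective_summit() - 1
    tad = tads.containing(site.chrom, summit0)
    if tad is None:
        return set()
    tree = loops.anchor_trees().get(site.chrom)
    if tree is None:
        return set()
    gene_trees = genes.interval_tree()
    out: set[str] = set()
    touched: dict[int, set[int]] = {}
    for _, _, (loop_i, side) in map(tuple, tree.overlap(site.start, site.end)):
        touched.setdefault(loop_i, set()).add(side)
    anchors = loops.df[LOOP_COLUMNS].to_numpy(dtype=object)
    for loop_i, sides in touched.items():
        # distal anchor = the side the site does not touch; if the site
        # touches both anchors, genes at either anchor qualify
        distal_sides = [s for s in (0, 1) if s not in sides] or [0, 1]
        for side in distal_sides:
            c, s, e = anchors[loop_i, 3 * side : 3 * side + 3]
            gtree = gene_trees.get(c)
            if gtree is None:
                continue
            for _, _, gene_id in map(tuple, gtree.overlap(int(s), int(e))):
                grow = genes.row_by_id(gene_id)
                if (
                    grow.chrom == tad.chrom
                    and grow.start < tad.end
                    and tad.start < grow.end
                ):
                    out.add(gene_id)
    return out


def proximity_target_genes(site, genes, distance: int) -> set[str]:
    """Genes overlapping summit ± distance (no loop or TAD condition)."""
    summit0 = site.effective_summit() - 1
    gtree = genes.interval_tree().get(site.chrom)
    if gtree is None:
        return set()
    return {
        gene_id
        for _, _, gene_id in map(
            tuple, gtree.overlap(summit0 - distance, summit0 + distance + 1)
        )
    }


MUTATION_GROUP_LABELS = ("0", "1", "2", "3+")


def group_sites_by_mutation_count(mut_counts) -> dict[str, np.ndarray]:
    """Site-index groups with 0, 1, 2, and >= 3 core mutations."""
    mut_counts = np.asarray(mut_counts)
    return {
        "0": np.flatnonzero(mut_counts == 0),
        "1": np.flatnonzero(mut_counts == 1),
        "2": np.flatnonzero(mut_counts == 2),
        "3+": np.flatnonzero(mut_counts >= 3),
    }


@dataclass
class ExpressionComparison:
    mode: str
    group_means: dict[str, np.ndarray]  # per group: n_gene_reps mean expressions
    pairwise: pd.DataFrame  # group_a, group_b, t_stat, p
    pool_sizes: dict[str, int] = field(default_factory=dict)

    def p_between(self, a: str, b: str) -> float:
        sel = self.pairwise[
            ((self.pairwise.group_a == a) & (self.pairwise.group_b == b))
            | ((self.pairwise.group_a == b) & (self.pairwise.group_b == a))
        ]
        return float(sel["p"].iloc[0])


def expression_by_mutation_group(
    sites,
    mut_counts,
    loops: LoopSet,
    tads: TADSet,
    genes,
    mode: str = "topological",
    n_region_sample: int = 500,
    n_region_reps: int = 10,
    n_gene_sample: int = 200,
    n_gene_reps: int = 100,
    seed: int | None = None,
) -> ExpressionComparison:
    """Compare target-gene expression across site mutation-count groups.

    Per group: sample n_region_sample sites n_region_reps times, pool the
    (deduplicated) target genes over all sampled regions, then draw
    n_gene_sample genes n_gene_reps times (without replacement within a
    draw), recording the mean expression per draw. Groups are compared by
    two-sided t-tests on the draw means.

    mode: 'topological' (loop + same-TAD), 'proximity_50kb' or
    'proximity_100kb' (linear distance only).
    """
    if mode not in ("topological", "proximity_50kb", "proximity_100kb"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_gene_reps < 2:
        raise ValueError("n_gene_reps must be >= 2 for a t-test on draw means")
    rng = np.random.default_rng(seed)
    groups = group_sites_by_mutation_count(mut_counts)
    expr = genes.df.set_index("gene_id")["expression"]
    group_means: dict[str, np.ndarray] = {}
    pool_sizes: dict[str, int] = {}
    for label, idx in groups.items():
        if len(idx) < n_region_sample:
            raise ValueError(
                f"group {label!r} has {len(idx)} sites, fewer than "
                f"n_region_sample={n_region_sample}"
            )
        pool: set[str] = set()
        per_site_cache: dict[int, frozenset] = {}
        dist = 50_000 if mode == "proximity_50kb" else 100_000
        for _ in range(n_region_reps):
            pick = rng.choice(idx, size=n_region_sample, replace=False)
            for si in pick:
                if si not in per_site_cache:
                    site = sites[si]
                    if mode == "topological":
                        targets = topo_target_genes(site, loops, tads, genes)
                    else:
                        targets = proximity_target_genes(site, genes, dist)
                    per_site_cache[si] = frozenset(targets)
                pool |= per_site_cache[si]
        if len(pool) < n_gene_sample:
            raise ValueError(
                f"group {label!r}: target-gene pool of {len(pool)} is smaller "
                f"than n_gene_sample={n_gene_sample}"
            )
        pool_arr = np.array(sorted(pool), dtype=object)
        pool_expr = expr.loc[pool_arr].to_numpy(dtype=float)
        means = np.empty(n_gene_reps)
        for r in range(n_gene_reps):
            pick = rng.choice(len(pool_arr), size=n_gene_sample, replace=False)
            means[r] = pool_expr[pick].mean()
        group_means[label] = means
        pool_sizes[label] = len(pool)
    rows = []
    labels = list(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t, p = stats.ttest_ind(group_means[a], group_means[b])
            rows.append((a, b, float(t), float(p)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t_stat", "p"])
    return ExpressionComparison(
        mode=mode, group_means=group_means, pairwise=pairwise, pool_sizes=pool_sizes
    )


def read_tads_bed(path) -> TADSet:
    from .intervals import read_interval_file

    return TADSet(read_interval_file(path, "bed3"))
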