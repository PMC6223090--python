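"""Allele counting at candidate positions from ChIP-seq alignments or a text
pileup, and the coverage/allele filter for potential somatic mutations.

A candidate site passes when it is covered by at least 10 reads and both the
reference and the alternative allele from the somatic catalog are observed
at least once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PILEUP_COLUMNS = ["chrom", "pos", "base", "baseq", "mapq", "sample"]

DEFAULT_MIN_BASEQ = 13
DEFAULT_MIN_MAPQ = 0


@dataclass
class AlleleCount:
    chrom: str
    pos: int  # 1-based
    depth: int
    counts: dict  # base -> count over {A, C, G, T}
    count_other: int = 0

    def __post_init__(self):
        total = sum(self.counts.values()) + self.count_other
        if total != self.depth:
            raise ValueError(
                f"depth {self.depth} != sum of base counts {total} at "
                f"{self.chrom}:{self.pos}"
            )


@dataclass
class PotentialSomaticCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    ref_count: int
    alt_count: int
    passes_filter: bool


def read_pileup_tsv(path) -> pd.DataFrame:
    """Read the documented per-read-base pileup TSV (one row per aligned base:
    chrom, pos, base, baseq, mapq, sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "base": str, "sample": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pileup column(s): {missing}")
    return df


def merge_pileups(pileups) -> pd.DataFrame:
    """Concatenate per-sample pileups (merged-group analysis)."""
    return pd.concat(list(pileups), ignore_index=True)


def count_alleles_from_pileup(
    pileup: pd.DataFrame,
    candidate_positions,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> dict:
    """Per-position base counts from a pileup table.

    ``candidate_positions`` is an iterable of (chrom, pos) with 1-based pos.
    Bases below the quality thresholds are dropped; non-ACGT entries (read
    deletions / reference skips, recorded as '*' or 'N') count toward
    count_other.
    """
    keep = (pileup["baseq"] >= min_baseq) & (pileup["mapq"] >= min_mapq)
    sub = pileup.loc[keep]
    grouped = sub.groupby(["chrom", "pos"])["base"]
    tallies = {key: grp.value_counts().to_dict() for key, grp in grouped}
    out = {}
    for chrom, pos in candidate_positions:
        tally = tallies.get((chrom, int(pos)), {})
        counts = {b: int(tally.get(b, 0)) for b in "ACGT"}
        other = int(sum(v for b, v in tally.items() if b not in "ACGT"))
        out[(chrom, int(pos))] = AlleleCount(
            chrom=chrom, pos=int(pos), depth=sum(counts.values()) + other,
            counts=counts, count_other=other,
        )
    return out


def count_alleles_from_sam(
    sam_path,
    candidate_positions,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    exclude_duplicates: bool = True,
) -> dict:
    """Per-position base counts by iterating a SAM/BAM file (no index needed).

    Each read contributes its aligned base at a candidate reference position
    once; reads with a deletion or reference skip at the position count
    toward count_other. Secondary/supplementary alignments and (by default)
    flagged duplicates are skipped.
    """
    import pysam

    wanted: dict[str, dict[int, list[int]]] = {}
    for chrom, pos in candidate_positions:
        wanted.setdefault(chrom, {})[int(pos) - 1] = [0, 0, 0, 0, 0]  # A C G T other
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        contig_lengths = dict(zip(fh.references, fh.lengths))
        for chrom, positions in wanted.items():
            length = contig_lengths.get(chrom)
            if length is not None:
                beyond = [p + 1 for p in positions if p >= length]
                if beyond:
                    raise ValueError(
                        f"candidate position(s) {beyond} beyond {chrom} length {length}"
                    )
        for read in fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if exclude_duplicates and read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            positions = wanted.get(read.reference_name)
            if not positions:
                continue
            quals = read.query_qualities
            seq = read.query_sequence
            covered = {
                rpos: qpos
                for qpos, rpos in read.get_aligned_pairs()
                if rpos in positions
            }
            for rpos, qpos in covered.items():
                slot = positions[rpos]
                if qpos is None:  # deletion or reference skip at the position
                    slot[4] += 1
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                slot[base_idx.get(seq[qpos].upper(), 4)] += 1
    out = {}
    for chrom, positions in wanted.items():
        for pos0, slot in positions.items():
            counts = {b: slot[i] for b, i in base_idx.items()}
            out[(chrom, pos0 + 1)] = AlleleCount(
                chrom=chrom, pos=pos0 + 1, depth=sum(slot), counts=counts,
                count_other=slot[4],
            )
    return out


def call_potential_somatic(
    counts: dict, known_alleles: dict, min_depth: int = 10
) -> list[PotentialSomaticCall]:
    """Apply the coverage/allele filter at candidate positions.

    ``known_alleles`` maps (chrom, pos) -> (ref, alt) from an external
    somatic catalog. A site passes when depth >= min_depth and both alleles
    are observed at least once.
    """
    calls = []
    for (chrom, pos), (ref, alt) in known_alleles.items():
        if ref == alt:
            raise ValueError(f"ref == alt ({ref}) at {chrom}:{pos}")
        ac = counts.get((chrom, pos))
        if ac is None:
            ac = AlleleCount(chrom, pos, 0, {b: 0 for b in "ACGT"})
        ref_count = ac.counts.get(ref, 0)
        alt_count = ac.counts.get(alt, 0)
        passes = ac.depth >= min_depth and ref_count >= 1 and alt_count >= 1
        calls.append(
            PotentialSomaticCall(
                chrom=chrom, pos=pos, ref=ref, alt=alt, depth=ac.depth,
                ref_count=ref_count, alt_count=alt_count, passes_filter=passes,
            )
        )
    return calls


def outcome_fraction(calls, site_of_position: dict, site_groups: dict) -> dict:
    """Fraction of sites per outcome class containing >= 1 passing call.

    ``site_of_position`` maps (chrom, pos) -> site_id; ``site_groups`` maps
    class label -> iterable of site_ids. An empty class yields NaN, not 0.
    """
    passing_sites = {
        site_of_position[(c.chrom, c.pos)]
        for c in calls
        if c.passes_filter and (c.chrom, c.pos) in site_of_position
    }
    out = {}
    for label, site_ids in site_groups.items():
        site_ids = list(site_ids)
        if not site_ids:
            out[label] = float("nan")
            continue
        hit = sum(1 for s in site_ids if s in passing_sites)
        out[label] = hit / len(site_ids)
    return out


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.pos, c.ref, c.alt, c.depth, c.ref_count, c.alt_count,
             c.passes_filter)
            for c in calls
        ],
        columns=["chrom", "pos", "ref", "alt", "depth", "ref_count", "alt_count",
                 "passes_filter"],
    )
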