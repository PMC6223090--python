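"""Genomic intervals, BED-family readers/writers, and multi-sample intersection.

Intervals are 0-based half-open (BED convention). Summits, when carried, are
1-based positions to match the mutation coordinate convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."
    score: float | None = None
    name: str | None = None
    summit: int | None = None  # 1-based, inside [start+1, end]

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start ({self.start}, {self.end})")

    @property
    def midpoint_summit(self) -> int:
        """1-based midpoint, ties to the lower coordinate."""
        return self.start + (self.end - self.start - 1) // 2 + 1

    def effective_summit(self) -> int:
        return self.summit if self.summit is not None else self.midpoint_summit

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}


def read_interval_file(path, dialect: str = "bed3") -> list[GenomicInterval]:
    """Parse a BED3/BED6/narrowPeak file into intervals.

    narrowPeak column 10 (summit offset from start) is retained as a 1-based
    summit when present and non-negative; otherwise the midpoint is used.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    min_cols = _DIALECT_MIN_COLS[dialect]
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= {min_cols} columns "
                    f"for {dialect}, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}: end <= start at line {lineno}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if dialect != "bed3" and len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            summit = None
            if dialect == "narrowPeak":
                if len(fields) > 6 and fields[6] not in (".", ""):
                    score = float(fields[6])  # signalValue preferred as intensity
                peak = int(fields[9])
                if peak >= 0:
                    summit = start + peak + 1
            out.append(
                GenomicInterval(
                    chrom=fields[0], start=start, end=end, strand=strand,
                    score=score, name=name, summit=summit,
                )
            )
    return out


def write_interval_file(intervals, path, dialect: str = "bed3") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                score = 0.0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score:g}\t{iv.strand}\n"
                )
            elif dialect == "narrowPeak":
                score = 0.0 if iv.score is None else iv.score
                peak = -1 if iv.summit is None else iv.summit - 1 - iv.start
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                    f"{iv.strand}\t{score:g}\t-1\t-1\t{peak}\n"
                )
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


@dataclass
class SharedSiteSet:
    """Maximal constant-membership segments from a multi-sample intersection.

    ``segments`` has columns chrom, start, end, sharing_count plus one boolean
    membership column per input sample.
    """

    segments: pd.DataFrame
    sample_names: list[str] = field(default_factory=list)

    @property
    def sharing_counts(self) -> np.ndarray:
        return self.segments["sharing_count"].to_numpy()


def multi_intersect(sample_interval_lists, sample_names=None) -> SharedSiteSet:
    """Partition the union of per-sample interval sets into segments of
    constant sample membership, recording how many samples cover each segment.

    Each sample's intervals are merged internally first; adjacent segments with
    identical membership are merged.
    """
    if not sample_interval_lists:
        raise ValueError("multi_intersect requires at least one sample")
    n = len(sample_interval_lists)
    if sample_names is None:
        sample_names = [f"sample_{i}" for i in range(n)]
    merged_per_sample = [merge_intervals(lst) if lst else [] for lst in sample_interval_lists]

    chroms = sorted({iv.chrom for lst in merged_per_sample for iv in lst})
    rows = []
    for chrom in chroms:
        events: dict[int, np.ndarray] = {}
        for si, lst in enumerate(merged_per_sample):
            for iv in lst:
                if iv.chrom != chrom:
                    continue
                for pos, delta in ((iv.start, 1), (iv.end, -1)):
                    if pos not in events:
                        events[pos] = np.zeros(n, dtype=np.int64)
                    events[pos][si] += delta
        positions = sorted(events)
        membership = np.zeros(n, dtype=np.int64)
        for left, right in zip(positions, positions[1:]):
            membership = membership + events[left]
            if membership.any():
                flags = membership > 0
                rows.append((chrom, left, right, int(flags.sum()), *flags.tolist()))
        # trailing events only close intervals; nothing extends past the last

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sharing_count", *sample_names])
    # merge adjacent segments with identical membership
    keep = []
    for i, row in df.iterrows():
        if keep:
            prev = keep[-1]
            if (
                prev["chrom"] == row["chrom"]
                and prev["end"] == row["start"]
                and all(prev[s] == row[s] for s in sample_names)
            ):
                prev["end"] = row["end"]
                continue
        keep.append(row.to_dict())
    out = pd.DataFrame(keep, columns=df.columns)
    return SharedSiteSet(segments=out, sample_names=list(sample_names))
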