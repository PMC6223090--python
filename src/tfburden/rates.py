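"""Observed and context-expected mutation-rate profiles around site summits.

The expected-rate model follows the mutational-signature convention: every
single-base substitution is assigned to one of 96 strand-collapsed
trinucleotide classes X[R>A]Y with a pyrimidine (C or T) reference center.
Expected rates come from repeatedly re-placing the observed per-class
mutation counts uniformly at random among valid window positions whose
reference trinucleotide matches the class, holding the 96 class counts fixed
in every resample, and averaging the per-offset placement counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Trinucleotide classes

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
PYRIMIDINES = "CT"

#: the 96 class labels in standard signature order:
#: ref in (C, T), alt ascending, then 5' and 3' context ascending.
CLASS_LABELS: list[str] = [
    f"{left}[{ref}>{alt}]{right}"
    for ref in PYRIMIDINES
    for alt in BASES
    if alt != ref
    for left in BASES
    for right in BASES
]
CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}

#: the 32 collapsed reference trinucleotides XRY (R pyrimidine), each hosting
#: three substitution classes.
TRINUC_LABELS: list[str] = [
    f"{left}{ref}{right}" for ref in PYRIMIDINES for left in BASES for right in BASES
]
N_CLASSES = 96
N_TRINUCS = 32

_CLASS_TO_TRINUC = np.empty(N_CLASSES, dtype=np.int64)
for _i, _lab in enumerate(CLASS_LABELS):
    _tri = _lab[0] + _lab[2] + _lab[6]
    _CLASS_TO_TRINUC[_i] = TRINUC_LABELS.index(_tri)


def class_to_trinuc(class_idx: int) -> int:
    """Collapsed-trinucleotide index (0..31) hosting a substitution class."""
    return int(_CLASS_TO_TRINUC[class_idx])


def _collapse(left: int, center: int, right: int, alt: int):
    """Map base codes to (trinuc_idx, class_idx); reverse-complement when the
    center is a purine. Returns None for N/invalid bases."""
    if min(left, center, right, alt) < 0:
        return None
    if center in (0, 2):  # A or G: reverse-complement
        left, center, right = 3 - right, 3 - center, 3 - left
        alt = 3 - alt
    cidx = 0 if center == 1 else 1  # C -> 0, T -> 1
    trinuc = cidx * 16 + left * 4 + right
    ref_base = BASES[center]
    alt_rank = sum(1 for b in BASES[: alt] if b != ref_base)
    class_idx = (cidx * 3 + alt_rank) * 16 + left * 4 + right
    return trinuc, class_idx


def classify_trinucleotide(genome, mutation) -> str | None:
    """96-class label of an SNV from its ±1 bp reference context.

    Purine-centered changes are reverse-complemented so the class is
    pyrimidine-centered; returns None when any context base is N.
    """
    if mutation.mut_type != "SNV":
        raise ValueError(f"classify_trinucleotide requires an SNV, got {mutation.mut_type}")
    pos0 = mutation.pos - 1
    if pos0 < 1 or pos0 > genome.chrom_length(mutation.chrom) - 2:
        raise ValueError(f"position {mutation.pos} too close to the {mutation.chrom} edge")
    ctx = genome.fetch(mutation.chrom, pos0 - 1, pos0 + 2)
    codes = [_CODE.get(b, -1) for b in ctx]
    alt = _CODE.get(mutation.alt, -1)
    res = _collapse(codes[0], codes[1], codes[2], alt)
    if res is None:
        return None
    return CLASS_LABELS[res[1]]


def classify_snvs(genome, chroms, positions, alts) -> np.ndarray:
    """Vectorized class indices for SNV arrays; -1 where unclassifiable."""
    positions = np.asarray(positions, dtype=np.int64)
    out = np.full(len(positions), -1, dtype=np.int64)
    chroms = np.asarray(chroms, dtype=object)
    alts = np.asarray(alts, dtype=object)
    for chrom in np.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        codes = genome.base_codes(chrom)
        pos0 = positions[sel] - 1
        ok = (pos0 >= 1) & (pos0 <= len(codes) - 2)
        for j in sel[~ok]:
            out[j] = -1
        idx = sel[ok]
        p = positions[idx] - 1
        left, center, right = codes[p - 1], codes[p], codes[p + 1]
        alt_codes = np.array([_CODE.get(a, -1) for a in alts[idx]], dtype=np.int64)
        purine = (center == 0) | (center == 2)
        l2 = np.where(purine, 3 - right, left)
        r2 = np.where(purine, 3 - left, right)
        c2 = np.where(purine, 3 - center, center)
        a2 = np.where(purine, 3 - alt_codes, alt_codes)
        valid = (left >= 0) & (center >= 0) & (right >= 0) & (alt_codes >= 0) & (a2 != c2)
        cidx = np.where(c2 == 1, 0, 1)
        # rank of the alt base among the three non-reference bases, ascending
        alt_rank = a2 - (a2 > c2).astype(np.int64)
        class_idx = (cidx * 3 + alt_rank) * 16 + l2 * 4 + r2
        out[idx] = np.where(valid, class_idx, -1)
    return out


def window_trinuc_codes(genome, windows) -> np.ndarray:
    """Collapsed trinucleotide index (0..31; -1 invalid) for every window
    position, shape (n_sites, 2*flank + 1)."""
    flank = windows.flank
    width = 2 * flank + 1
    out = np.full((windows.n_sites, width), -1, dtype=np.int64)
    codes_cache: dict[str, np.ndarray] = {}
    for i in range(windows.n_sites):
        chrom = windows.chroms[i]
        if chrom not in codes_cache:
            codes_cache[chrom] = genome.base_codes(chrom)
        codes = codes_cache[chrom]
        center0 = windows.summits[i] - 1
        lo, hi = center0 - flank - 1, center0 + flank + 2
        if lo < 0 or hi > len(codes):
            # pad windows running off the chromosome edge with N
            arr = np.full(hi - lo, -1, dtype=np.int64)
            src_lo, src_hi = max(lo, 0), min(hi, len(codes))
            arr[src_lo - lo : src_hi - lo] = codes[src_lo:src_hi]
        else:
            arr = codes[lo:hi]
        left, center, right = arr[:-2], arr[1:-1], arr[2:]
        purine = (center == 0) | (center == 2)
        l2 = np.where(purine, 3 - right, left)
        r2 = np.where(purine, 3 - left, right)
        c2 = np.where(purine, 3 - center, center)
        valid = (left >= 0) & (center >= 0) & (right >= 0)
        cidx = np.where(c2 == 1, 0, 1)
        tri = cidx * 16 + l2 * 4 + r2
        out[i] = np.where(valid, tri, -1)
    return out


# ---------------------------------------------------------------------------
# Mapping mutations into windows


def assign_mutations(windows, chroms, positions):
    """Map 1-based mutation positions into summit windows.

    Returns (mut_idx, site_idx, offset) arrays; a mutation falling inside
    several overlapping windows contributes one row per window.
    """
    positions = np.asarray(positions, dtype=np.int64)
    chroms = np.asarray(chroms, dtype=object)
    flank = windows.flank
    mut_rows, site_rows, off_rows = [], [], []
    site_chroms = windows.chroms
    for chrom in np.unique(chroms):
        site_sel = np.flatnonzero(site_chroms == chrom)
        if len(site_sel) == 0:
            continue
        order = np.argsort(windows.summits[site_sel], kind="stable")
        site_sel = site_sel[order]
        summits = windows.summits[site_sel]
        msel = np.flatnonzero(chroms == chrom)
        pos = positions[msel]
        lo = np.searchsorted(summits, pos - flank, side="left")
        hi = np.searchsorted(summits, pos + flank, side="right")
        single = hi - lo == 1
        mut_rows.append(msel[single])
        site_rows.append(site_sel[lo[single]])
        off_rows.append(pos[single] - summits[lo[single]])
        for j in np.flatnonzero(hi - lo > 1):
            for k in range(lo[j], hi[j]):
                mut_rows.append(np.array([msel[j]]))
                site_rows.append(np.array([site_sel[k]]))
                off_rows.append(np.array([pos[j] - summits[k]]))
    if not mut_rows:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    return (
        np.concatenate(mut_rows),
        np.concatenate(site_rows),
        np.concatenate(off_rows),
    )


def in_window_snvs(windows, mutations, respect_mask: bool = True):
    """(row_index, site_idx, offset) of SNVs landing at valid window positions."""
    df = mutations.snvs.df
    mut_idx, site_idx, offset = assign_mutations(
        windows, df["chrom"].to_numpy(), df["pos"].to_numpy()
    )
    if respect_mask and len(mut_idx):
        keep = windows.valid_mask[site_idx, offset + windows.flank]
        mut_idx, site_idx, offset = mut_idx[keep], site_idx[keep], offset[keep]
    return df, mut_idx, site_idx, offset


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class RateProfile:
    """Per-offset mutation rates around summits.

    ``observed_rate``/``expected_rate`` are mutations per valid position per
    offset; offsets with zero valid positions carry NaN (missing), never 0.
    """

    offsets: np.ndarray
    n_sites: int
    n_valid: np.ndarray
    observed_counts: np.ndarray | None = None
    observed_rate: np.ndarray | None = None
    expected_counts: np.ndarray | None = None
    expected_rate: np.ndarray | None = None

    def total_observed(self) -> int:
        return int(self.observed_counts.sum()) if self.observed_counts is not None else 0

    def to_frame(self):
        import pandas as pd

        data = {"offset": self.offsets, "n_valid": self.n_valid}
        if self.observed_counts is not None:
            data["observed_count"] = self.observed_counts
            data["observed_rate"] = self.observed_rate
        if self.expected_rate is not None:
            data["expected_rate"] = self.expected_rate
        return pd.DataFrame(data)


def observed_rate_profile(windows, mutations, mut_types=("SNV",)) -> RateProfile:
    """Per-offset observed mutation rate over valid window positions.

    Indels are assigned to their 1-based start position; mutations at masked
    positions are ignored. The rate at an offset with zero valid positions is
    recorded as NaN.
    """
    table = mutations.of_type(*mut_types)
    df = table.df
    mut_idx, site_idx, offset = assign_mutations(
        windows, df["chrom"].to_numpy(), df["pos"].to_numpy()
    )
    width = 2 * windows.flank + 1
    counts = np.zeros(width, dtype=np.int64)
    if len(mut_idx):
        cols = offset + windows.flank
        keep = windows.valid_mask[site_idx, cols]
        counts = np.bincount(cols[keep], minlength=width)
    n_valid = windows.n_valid_per_offset()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_valid > 0, counts / np.maximum(n_valid, 1), np.nan)
    return RateProfile(
        offsets=windows.offsets,
        n_sites=windows.n_sites,
        n_valid=n_valid,
        observed_counts=counts,
        observed_rate=rate,
    )


@dataclass
class TrinucleotideModel:
    """Probabilities (and source counts) of the 96 substitution classes."""

    probs: np.ndarray
    counts: np.ndarray
    n_unclassifiable: int = 0

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.probs.shape != (N_CLASSES,):
            raise ValueError("probs must have exactly 96 entries")
        if (self.probs < 0).any():
            raise ValueError("probs must be non-negative")
        if not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("probs must sum to 1")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"class": CLASS_LABELS, "count": self.counts, "probability": self.probs}
        )

    @classmethod
    def read_tsv(cls, path):
        import pandas as pd

        df = pd.read_csv(path, sep="\t").set_index("class")
        counts = df.loc[CLASS_LABELS, "count"].to_numpy()
        probs = df.loc[CLASS_LABELS, "probability"].to_numpy()
        return cls(probs=probs, counts=counts)

    def write_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_trinucleotide_model(mutations, genome, windows) -> TrinucleotideModel:
    """Class frequencies of SNVs at valid window positions, normalized to 1.

    SNVs with undefined context (N bases) are excluded and counted.
    """
    df, mut_idx, _, _ = in_window_snvs(windows, mutations)
    if len(mut_idx) == 0:
        raise ValueError("no SNVs fall inside the analysis windows")
    sub = df.iloc[mut_idx]
    cls = classify_snvs(
        genome, sub["chrom"].to_numpy(), sub["pos"].to_numpy(), sub["alt"].to_numpy()
    )
    n_bad = int((cls < 0).sum())
    cls = cls[cls >= 0]
    if len(cls) == 0:
        raise ValueError("no classifiable SNVs inside the analysis windows")
    counts = np.bincount(cls, minlength=N_CLASSES)
    return TrinucleotideModel(
        probs=counts / counts.sum(), counts=counts, n_unclassifiable=n_bad
    )


def expected_rate_profile(
    windows,
    genome,
    model: TrinucleotideModel,
    n_resamples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RateProfile:
    """Context-matched expected rate by repeated random placement.

    Each resample places exactly the model's observed count of every class
    uniformly at random, without replacement, among valid window positions
    whose reference trinucleotide matches the class. Only per-offset counts
    are needed, so the placement is drawn per collapsed trinucleotide as a
    multivariate hypergeometric over offset bins — distributionally identical
    to sampling positions uniformly without replacement.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    width = 2 * windows.flank + 1
    tri = window_trinuc_codes(genome, windows)
    tri = np.where(windows.valid_mask, tri, -1)
    # positions available per (trinuc, offset)
    pools = np.zeros((N_TRINUCS, width), dtype=np.int64)
    for t in range(N_TRINUCS):
        pools[t] = (tri == t).sum(axis=0)
    draw_per_trinuc = np.zeros(N_TRINUCS, dtype=np.int64)
    for ci in range(N_CLASSES):
        draw_per_trinuc[_CLASS_TO_TRINUC[ci]] += model.counts[ci]
    for t in range(N_TRINUCS):
        if draw_per_trinuc[t] > pools[t].sum():
            offending = [
                CLASS_LABELS[ci]
                for ci in range(N_CLASSES)
                if _CLASS_TO_TRINUC[ci] == t and model.counts[ci] > 0
            ]
            raise ValueError(
                f"classes {offending} require {draw_per_trinuc[t]} placements but "
                f"only {pools[t].sum()} positions with context {TRINUC_LABELS[t]} exist"
            )
    total = np.zeros(width, dtype=np.int64)
    active = [t for t in range(N_TRINUCS) if draw_per_trinuc[t] > 0]
    for _ in range(n_resamples):
        for t in active:
            total += rng.multivariate_hypergeometric(pools[t], int(draw_per_trinuc[t]))
    expected_counts = total / n_resamples
    n_valid = windows.n_valid_per_offset()
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_valid > 0, expected_counts / np.maximum(n_valid, 1), np.nan)
    return RateProfile(
        offsets=windows.offsets,
        n_sites=windows.n_sites,
        n_valid=n_valid,
        expected_counts=expected_counts,
        expected_rate=rate,
    )
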