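"""Summit-centered analysis windows with exclusion masks, and genomic-context
annotation of sites relative to a gene table.

A window extends ``flank`` bp on both sides of a site summit (1 kb for
substitution analyses, 5 kb for indels). Positions overlapping coding
sequence, blacklisted, or low-mappability regions are masked everywhere in
the window and sites whose core overlaps such a region are dropped; other-TF
binding sites mask only flank positions (|offset| > core half-width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import GenomicInterval, merge_intervals

HARD_EXCLUSION_KEYS = ("coding", "blacklist", "low_mappability")
FLANK_EXCLUSION_KEY = "other_tf_flank"


@dataclass
class SummitWindowSet:
    site_ids: list
    chroms: np.ndarray  # per site
    summits: np.ndarray  # 1-based, per site
    flank: int
    valid_mask: np.ndarray  # n_sites x (2*flank + 1)
    scores: np.ndarray | None = None  # optional binding intensity per site

    def __post_init__(self):
        self.summits = np.asarray(self.summits, dtype=np.int64)
        self.chroms = np.asarray(self.chroms, dtype=object)
        n = len(self.site_ids)
        if self.valid_mask.shape != (n, 2 * self.flank + 1):
            raise ValueError(
                f"valid_mask shape {self.valid_mask.shape} != "
                f"({n}, {2 * self.flank + 1})"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def n_valid_per_offset(self) -> np.ndarray:
        return self.valid_mask.sum(axis=0)

    def subset(self, indices) -> "SummitWindowSet":
        indices = np.asarray(indices)
        return SummitWindowSet(
            site_ids=[self.site_ids[i] for i in indices],
            chroms=self.chroms[indices],
            summits=self.summits[indices],
            flank=self.flank,
            valid_mask=self.valid_mask[indices],
            scores=None if self.scores is None else self.scores[indices],
        )


def _merged_arrays(intervals) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(intervals) if intervals else []
    out: dict[str, list[list[int]]] = {}
    for iv in merged:
        out.setdefault(iv.chrom, [[], []])
        out[iv.chrom][0].append(iv.start)
        out[iv.chrom][1].append(iv.end)
    return {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()}


def _covered_offsets(chrom_arrays, chrom, window0, width) -> np.ndarray:
    """Boolean vector over window offsets covered by an exclusion set.

    ``window0`` is the 0-based coordinate of the leftmost window position.
    """
    covered = np.zeros(width, dtype=bool)
    if chrom not in chrom_arrays:
        return covered
    starts, ends = chrom_arrays[chrom]
    i = int(np.searchsorted(ends, window0, side="right"))
    while i < len(starts) and starts[i] < window0 + width:
        lo = max(int(starts[i]), window0) - window0
        hi = min(int(ends[i]), window0 + width) - window0
        covered[lo:hi] = True
        i += 1
    return covered


def build_analysis_windows(
    sites,
    flank: int,
    exclude_sets: dict | None = None,
    core_halfwidth: int = 200,
    drop_excluded_core: bool = True,
) -> SummitWindowSet:
    """Extend site summits to ±flank windows and apply exclusion filters.

    ``exclude_sets`` maps {'coding', 'blacklist', 'low_mappability',
    'other_tf_flank'} to interval lists. The first three mask any overlapped
    window position and (by default) drop sites whose ±core_halfwidth core is
    touched; other-TF sites mask only positions with |offset| > core_halfwidth.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    exclude_sets = exclude_sets or {}
    width = 2 * flank + 1
    offsets = np.arange(-flank, flank + 1)
    core_cols = np.abs(offsets) <= core_halfwidth

    hard = {
        key: _merged_arrays(exclude_sets[key])
        for key in HARD_EXCLUSION_KEYS
        if key in exclude_sets and exclude_sets[key]
    }
    other_tf = (
        _merged_arrays(exclude_sets[FLANK_EXCLUSION_KEY])
        if exclude_sets.get(FLANK_EXCLUSION_KEY)
        else None
    )

    site_ids, chroms, summits, scores, masks = [], [], [], [], []
    have_scores = False
    for idx, site in enumerate(sites):
        summit = site.effective_summit()
        if not (site.start + 1 <= summit <= site.end):
            raise ValueError(
                f"summit {summit} outside source interval "
                f"{site.chrom}:[{site.start},{site.end})"
            )
        window0 = summit - 1 - flank  # 0-based leftmost position
        mask = np.ones(width, dtype=bool)
        drop = False
        for arrays in hard.values():
            covered = _covered_offsets(arrays, site.chrom, window0, width)
            if drop_excluded_core and (covered & core_cols).any():
                drop = True
                break
            mask &= ~covered
        if drop:
            continue
        if other_tf is not None:
            covered = _covered_offsets(other_tf, site.chrom, window0, width)
            mask &= ~(covered & ~core_cols)
        site_ids.append(site.name if site.name is not None else idx)
        chroms.append(site.chrom)
        summits.append(summit)
        scores.append(site.score)
        if site.score is not None:
            have_scores = True
        masks.append(mask)

    return SummitWindowSet(
        site_ids=site_ids,
        chroms=np.asarray(chroms, dtype=object),
        summits=np.asarray(summits, dtype=np.int64),
        flank=flank,
        valid_mask=(
            np.asarray(masks) if masks else np.zeros((0, width), dtype=bool)
        ),
        scores=np.asarray(scores, dtype=float) if have_scores else None,
    )


def annotate_genomic_context(
    sites,
    gene_table,
    promoter_upstream_bp: int = 2000,
    promoter_downstream_bp: int = 500,
) -> list[str]:
    """Label each site summit promoter / intronic / intergenic.

    Promoter: summit within [TSS - upstream, TSS + downstream] respecting
    strand. Intronic: summit inside a gene body. Precedence promoter >
    intronic > intergenic.
    """
    genes = gene_table.df
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    labels = []
    for site in sites:
        summit0 = site.effective_summit() - 1  # 0-based
        g = by_chrom.get(site.chrom)
        if g is None:
            labels.append("intergenic")
            continue
        tss = g["tss"].to_numpy()
        minus = (g["strand"] == "-").to_numpy()
        prom_lo = np.where(minus, tss - promoter_downstream_bp, tss - promoter_upstream_bp)
        prom_hi = np.where(minus, tss + promoter_upstream_bp, tss + promoter_downstream_bp)
        if ((summit0 >= prom_lo) & (summit0 <= prom_hi)).any():
            labels.append("promoter")
        elif ((summit0 >= g["start"].to_numpy()) & (summit0 < g["end"].to_numpy())).any():
            labels.append("intronic")
        else:
            labels.append("intergenic")
    return labels
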