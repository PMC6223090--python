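"""Core-vs-flank enrichment tests and stratified burden analyses.

The enrichment statistic contrasts the per-position mutation rate within
±core_halfwidth of the summit (the core) against the flank band
(core_halfwidth, flank] on both sides, as a 2×2 contingency table of
mutation counts versus valid positions, tested with a Pearson chi-square and
Benjamini-Hochberg corrected within one analysis family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rates import (
    RateProfile,
    assign_mutations,
    in_window_snvs,
    observed_rate_profile,
)


@dataclass
class EnrichmentResult:
    fold_change: float
    chi2_stat: float
    p_value: float
    core_mut: int
    core_pos: int
    flank_mut: int
    flank_pos: int
    q_value: float | None = None
    fc_defined: bool = True

    @property
    def core_rate(self) -> float:
        return self.core_mut / self.core_pos

    @property
    def flank_rate(self) -> float:
        return self.flank_mut / self.flank_pos


def enrichment_test(
    core_mut: int,
    core_pos: int,
    flank_mut: int,
    flank_pos: int,
    continuity_correction: bool = False,
) -> EnrichmentResult:
    """Pearson chi-square on [[core_mut, core_pos-core_mut],
    [flank_mut, flank_pos-flank_mut]] plus the rate fold change.

    No continuity correction by default (counts are large in intended use).
    A zero flank count leaves the fold change undefined (NaN, flagged).
    """
    cells = np.array(
        [
            [core_mut, core_pos - core_mut],
            [flank_mut, flank_pos - flank_mut],
        ],
        dtype=float,
    )
    if (cells < 0).any():
        raise ValueError(f"negative contingency cell in {cells.tolist()}")
    if core_pos < 1 or flank_pos < 1:
        raise ValueError("core and flank must each have at least one valid position")
    if cells.sum(axis=0).min() == 0 or cells.sum(axis=1).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency(cells, correction=continuity_correction)
    if flank_mut > 0:
        fc = (core_mut / core_pos) / (flank_mut / flank_pos)
        defined = True
    else:
        fc, defined = float("nan"), False
    return EnrichmentResult(
        fold_change=fc, chi2_stat=float(chi2), p_value=float(p),
        core_mut=int(core_mut), core_pos=int(core_pos),
        flank_mut=int(flank_mut), flank_pos=int(flank_pos), fc_defined=defined,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for one test family."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def core_flank_counts(profile: RateProfile, core_halfwidth: int = 200,
                      flank_range: tuple[int, int] = (200, 1000)):
    """(core_mut, core_pos, flank_mut, flank_pos) from an observed profile."""
    off = np.abs(profile.offsets)
    core = off <= core_halfwidth
    flank = (off > flank_range[0]) & (off <= flank_range[1])
    counts = profile.observed_counts
    return (
        int(counts[core].sum()),
        int(profile.n_valid[core].sum()),
        int(counts[flank].sum()),
        int(profile.n_valid[flank].sum()),
    )


def enrichment_from_windows(
    windows, mutations, mut_types=("SNV",), core_halfwidth: int = 200,
    flank_range: tuple[int, int] = (200, 1000), continuity_correction: bool = False,
) -> EnrichmentResult:
    profile = observed_rate_profile(windows, mutations, mut_types=mut_types)
    return enrichment_test(
        *core_flank_counts(profile, core_halfwidth, flank_range),
        continuity_correction=continuity_correction,
    )


# ---------------------------------------------------------------------------
# Substitution spectrum (six pyrimidine-collapsed classes)

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_substitution(ref: str, alt: str) -> str | None:
    """Six-class pyrimidine-collapsed label of a single-base substitution."""
    if ref in "AG":
        ref, alt = _COMP.get(ref, "N"), _COMP.get(alt, "N")
    label = f"{ref}>{alt}"
    return label if label in SPECTRUM_CLASSES else None


@dataclass
class SpectrumResult:
    table: pd.DataFrame  # class, core_count, flank_count, fold_change, chi2, p, q

    @property
    def total_snvs(self) -> int:
        return int(self.table[["core_count", "flank_count"]].to_numpy().sum())


def substitution_spectrum(
    windows, mutations, core_halfwidth: int = 200,
    flank_range: tuple[int, int] = (200, 1000),
) -> SpectrumResult:
    """Six-class counts in core and flank with per-class enrichment tests,
    BH-corrected across the six classes."""
    df, mut_idx, _site_idx, offset = in_window_snvs(windows, mutations)
    sub = df.iloc[mut_idx]
    labels = np.array(
        [collapse_substitution(r, a) or "" for r, a in zip(sub["ref"], sub["alt"])],
        dtype=object,
    )
    absoff = np.abs(offset)
    in_core = absoff <= core_halfwidth
    in_flank = (absoff > flank_range[0]) & (absoff <= flank_range[1])
    n_valid = windows.n_valid_per_offset()
    off = np.abs(windows.offsets)
    core_pos = int(n_valid[off <= core_halfwidth].sum())
    flank_pos = int(n_valid[(off > flank_range[0]) & (off <= flank_range[1])].sum())
    rows = []
    for cls in SPECTRUM_CLASSES:
        sel = labels == cls
        cm = int((sel & in_core).sum())
        fm = int((sel & in_flank).sum())
        res = enrichment_test(cm, core_pos, fm, flank_pos)
        rows.append((cls, cm, fm, res.fold_change, res.chi2_stat, res.p_value))
    table = pd.DataFrame(
        rows, columns=["class", "core_count", "flank_count", "fold_change", "chi2", "p"]
    )
    table["q"] = bh_adjust(table["p"])
    return SpectrumResult(table=table)


# ---------------------------------------------------------------------------
# Stratified analyses


@dataclass
class StratifiedGroups:
    key: str
    labels: list[str]
    site_indices: dict[str, np.ndarray]
    results: dict[str, EnrichmentResult]
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in self.labels:
            r = self.results[label]
            rows.append(
                (label, len(self.site_indices[label]), r.core_mut, r.core_pos,
                 r.flank_mut, r.flank_pos, r.fold_change, r.chi2_stat,
                 r.p_value, r.q_value)
            )
        return pd.DataFrame(
            rows,
            columns=["group", "n_sites", "core_mut", "core_pos", "flank_mut",
                     "flank_pos", "fold_change", "chi2", "p", "q"],
        )


def _grouped_enrichment(windows, mutations, site_indices, key, mut_types=("SNV",),
                        core_halfwidth=200, flank_range=(200, 1000), extra=None):
    results = {}
    for label, idx in site_indices.items():
        results[label] = enrichment_from_windows(
            windows.subset(idx), mutations, mut_types=mut_types,
            core_halfwidth=core_halfwidth, flank_range=flank_range,
        )
    qs = bh_adjust([results[label].p_value for label in site_indices])
    for label, q in zip(site_indices, qs):
        results[label].q_value = float(q)
    return StratifiedGroups(
        key=key, labels=list(site_indices), site_indices=site_indices,
        results=results, extra=extra or {},
    )


def stratify_by_quantile(
    windows, mutations, values, k: int = 4, mut_types=("SNV",),
    core_halfwidth: int = 200, flank_range: tuple[int, int] = (200, 1000),
) -> StratifiedGroups:
    """Split sites into k value quantiles (e.g. binding-intensity quartiles)
    and test enrichment per group.

    Also reports the Pearson correlation between per-group mean value and
    per-group core mutation rate. Ties across quantile edges fall back to a
    stable-order split with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = windows.n_sites
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of sites ({n})")
    edges = np.quantile(values, np.linspace(0, 1, k + 1))
    if len(np.unique(edges)) < k + 1:
        warnings.warn("tied quantile edges; falling back to stable-order split")
        order = np.argsort(values, kind="stable")
        assignment = np.empty(n, dtype=np.int64)
        assignment[order] = (np.arange(n) * k) // n
    else:
        assignment = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, k - 1)
    site_indices = {f"q{g + 1}": np.flatnonzero(assignment == g) for g in range(k)}
    groups = _grouped_enrichment(
        windows, mutations, site_indices, key="intensity_quartile",
        mut_types=mut_types, core_halfwidth=core_halfwidth, flank_range=flank_range,
    )
    mean_vals = [values[site_indices[lab]].mean() for lab in groups.labels]
    core_rates = [groups.results[lab].core_rate for lab in groups.labels]
    r, _ = stats.pearsonr(mean_vals, core_rates)
    groups.extra["pearson_r"] = float(r)
    groups.extra["group_mean_value"] = mean_vals
    groups.extra["group_core_rate"] = core_rates
    return groups


DEFAULT_SHARING_CLASSES = (
    ("patient_specific", 1, 1),
    ("shared_2_3", 2, 3),
    ("shared_gt3", 4, np.inf),
)


def stratify_by_sharing(
    windows, mutations, sharing_counts, classes=DEFAULT_SHARING_CLASSES,
    mut_types=("SNV",), core_halfwidth: int = 200,
    flank_range: tuple[int, int] = (200, 1000),
) -> StratifiedGroups:
    """Group sites by the number of patients sharing them and test enrichment
    per class. Default classes: patient-specific (1), shared by 2-3, shared
    by more than 3; edges configurable."""
    sharing = np.asarray(sharing_counts)
    site_indices = {
        label: np.flatnonzero((sharing >= lo) & (sharing <= hi))
        for label, lo, hi in classes
    }
    site_indices = {lab: idx for lab, idx in site_indices.items() if len(idx)}
    return _grouped_enrichment(
        windows, mutations, site_indices, key="sharing_class",
        mut_types=mut_types, core_halfwidth=core_halfwidth, flank_range=flank_range,
    )


def stratify_by_label(
    windows, mutations, labels, key: str = "context", mut_types=("SNV",),
    core_halfwidth: int = 200, flank_range: tuple[int, int] = (200, 1000),
) -> StratifiedGroups:
    """Enrichment per categorical site label (genomic context, outcome class,
    control-tissue subgroup ...)."""
    labels = np.asarray(labels, dtype=object)
    site_indices = {
        str(lab): np.flatnonzero(labels == lab) for lab in pd.unique(labels)
    }
    return _grouped_enrichment(
        windows, mutations, site_indices, key=key, mut_types=mut_types,
        core_halfwidth=core_halfwidth, flank_range=flank_range,
    )


# ---------------------------------------------------------------------------
# Per-site burden, outcome comparison, ranking


def core_mutation_table(windows, mutations, core_halfwidth: int = 200,
                        mut_types=("SNV",)) -> pd.DataFrame:
    """Long table of mutations within ±core_halfwidth of summits at valid
    positions: one row per (site, mutation) with donor and allele columns."""
    table = mutations.of_type(*mut_types)
    df = table.df
    mut_idx, site_idx, offset = assign_mutations(
        windows, df["chrom"].to_numpy(), df["pos"].to_numpy()
    )
    if len(mut_idx):
        keep = (np.abs(offset) <= core_halfwidth) & windows.valid_mask[
            site_idx, offset + windows.flank
        ]
        mut_idx, site_idx, offset = mut_idx[keep], site_idx[keep], offset[keep]
    sub = df.iloc[mut_idx].reset_index(drop=True)
    sub["site_index"] = site_idx
    sub["offset"] = offset
    return sub


def core_mutation_counts(windows, mutations, core_halfwidth: int = 200,
                         mut_types=("SNV",)) -> np.ndarray:
    """Mutations per site within the core, valid positions only."""
    long = core_mutation_table(windows, mutations, core_halfwidth, mut_types)
    return np.bincount(long["site_index"], minlength=windows.n_sites)


def outcome_burden_test(
    group_windows: dict, mutations, n_sample: int = 100, n_reps: int = 50,
    core_halfwidth: int = 200, seed: int | None = None,
) -> pd.DataFrame:
    """Mean core mutation burden per outcome group by repeated site sampling.

    Per repetition, n_sample sites are drawn without replacement from each
    group and the mean core mutation count recorded; groups are compared by
    two-sided t-tests on the repetition means.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a t-test on repetition means")
    rng = np.random.default_rng(seed)
    rep_means: dict[str, np.ndarray] = {}
    for label, win in group_windows.items():
        if win.n_sites < n_sample:
            raise ValueError(
                f"group {label!r} has {win.n_sites} sites, fewer than n_sample={n_sample}"
            )
        counts = core_mutation_counts(win, mutations, core_halfwidth)
        means = np.empty(n_reps)
        for r in range(n_reps):
            pick = rng.choice(win.n_sites, size=n_sample, replace=False)
            means[r] = counts[pick].mean()
        rep_means[label] = means
    rows = []
    labels = list(group_windows)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            t, p = stats.ttest_ind(rep_means[a], rep_means[b])
            rows.append((a, b, rep_means[a].mean(), rep_means[b].mean(), float(t), float(p)))
    out = pd.DataFrame(
        rows, columns=["group_a", "group_b", "mean_a", "mean_b", "t_stat", "p"]
    )
    out.attrs["rep_means"] = rep_means
    return out


def rank_sites_by_burden(windows, mutations, core_halfwidth: int = 200,
                         mut_types=("SNV",)) -> pd.DataFrame:
    """Sites ordered by core mutation count, with distinct-donor counts and a
    recurrent flag (some exact (pos, ref, alt) seen in ≥ 2 distinct donors)."""
    long = core_mutation_table(windows, mutations, core_halfwidth, mut_types)
    n = windows.n_sites
    counts = np.bincount(long["site_index"], minlength=n)
    donors = long.groupby("site_index")["donor_id"].nunique()
    n_donors = np.zeros(n, dtype=np.int64)
    n_donors[donors.index] = donors.to_numpy()
    recurrent = np.zeros(n, dtype=bool)
    if len(long):
        per_variant = long.groupby(["site_index", "pos", "ref", "alt"])["donor_id"].nunique()
        hot = per_variant[per_variant >= 2].reset_index()["site_index"].unique()
        recurrent[hot] = True
    out = pd.DataFrame(
        {
            "site_id": windows.site_ids,
            "n_mutations": counts,
            "n_donors": n_donors,
            "has_recurrent": recurrent,
        }
    )
    return out.sort_values(
        ["n_mutations", "n_donors"], ascending=False, kind="stable"
    ).reset_index(drop=True)
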