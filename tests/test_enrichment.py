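"""Core-vs-flank enrichment statistics and stratified burden analyses."""

import numpy as np
import pandas as pd
import pytest

from tfburden.enrichment import (
    bh_adjust,
    core_flank_counts,
    core_mutation_counts,
    enrichment_from_windows,
    enrichment_test,
    outcome_burden_test,
    rank_sites_by_burden,
    stratify_by_label,
    stratify_by_quantile,
    stratify_by_sharing,
    substitution_spectrum,
    collapse_substitution,
)
from tfburden.intervals import GenomicInterval
from tfburden.mutations import MutationTable
from tfburden.rates import observed_rate_profile
from tfburden.windows import build_analysis_windows


def chi2_by_hand(table):
    """Textbook Pearson chi-square for a 2x2 table."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    return ((table - expected) ** 2 / expected).sum()


def mutation_table(rows):
    return MutationTable(
        pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "donor_id",
                                    "mut_type"])
    )


class TestEnrichmentTest:
    def test_identical_rates_give_unity_fold_change(self):
        res = enrichment_test(4, 1000, 4, 1000)
        assert res.fold_change == 1.0
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_statistic_matches_textbook_formula(self):
        res = enrichment_test(20, 1000, 10, 1000)
        assert res.fold_change == 2.0
        expected = chi2_by_hand([[20, 980], [10, 990]])
        assert res.chi2_stat == pytest.approx(expected, rel=1e-12)
        from scipy.stats import chi2 as chi2_dist

        assert res.p_value == pytest.approx(chi2_dist.sf(expected, 1), rel=1e-9)

    def test_zero_flank_mutations_flags_undefined_fc(self):
        res = enrichment_test(5, 100, 0, 100)
        assert not res.fc_defined and np.isnan(res.fold_change)

    def test_negative_cell_is_an_error(self):
        with pytest.raises(ValueError):
            enrichment_test(10, 5, 1, 100)

    def test_bh_closed_form(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_bh_is_monotone_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestCoreFlankCounts:
    def test_counts_partition_profile(self, small_world, small_windows):
        prof = observed_rate_profile(small_windows, small_world["mutations"])
        cm, cp, fm, fp = core_flank_counts(prof, 200, (200, 1000))
        off = np.abs(prof.offsets)
        assert cm == prof.observed_counts[off <= 200].sum()
        assert fm == prof.observed_counts[(off > 200) & (off <= 1000)].sum()
        assert cp == prof.n_valid[off <= 200].sum()
        assert fp == prof.n_valid[(off > 200) & (off <= 1000)].sum()

    def test_planted_enrichment_recovered(self, small_world, small_windows):
        res = enrichment_from_windows(small_windows, small_world["mutations"])
        assert 1.1 < res.fold_change < 1.45
        assert res.p_value < 1e-4


class TestSpectrum:
    def test_purine_changes_collapse(self):
        assert collapse_substitution("G", "A") == "C>T"
        assert collapse_substitution("C", "T") == "C>T"
        assert collapse_substitution("A", "C") == "T>G"

    def test_class_totals_match_brute_force(self, small_world, small_windows):
        spec = substitution_spectrum(small_windows, small_world["mutations"])
        # oracle: count collapsed classes among in-core/in-flank SNVs by hand
        df = small_world["mutations"].snvs.df
        summits = {
            (small_windows.chroms[i], small_windows.summits[i])
            for i in range(small_windows.n_sites)
        }
        core, flank = {}, {}
        for row in df.itertuples(index=False):
            for chrom, s in summits:
                if chrom != row.chrom:
                    continue
                d = abs(row.pos - s)
                if d <= 1000:
                    cls = collapse_substitution(row.ref, row.alt)
                    if d <= 200:
                        core[cls] = core.get(cls, 0) + 1
                    elif d > 200:
                        flank[cls] = flank.get(cls, 0) + 1
        tab = spec.table.set_index("class")
        for cls in tab.index:
            assert tab.loc[cls, "core_count"] == core.get(cls, 0)
            assert tab.loc[cls, "flank_count"] == flank.get(cls, 0)

    def test_apobec_classes_dominate_on_default_signature(self, small_world,
                                                          small_windows):
        spec = substitution_spectrum(small_windows, small_world["mutations"])
        tab = spec.table.set_index("class")
        cg_ct = tab.loc[["C>G", "C>T"], ["core_count", "flank_count"]].sum().sum()
        assert cg_ct / spec.total_snvs > 0.5


class TestStratifyByQuantile:
    def test_even_split_on_distinct_values(self, small_world, small_windows):
        values = np.arange(small_windows.n_sites, dtype=float)
        groups = stratify_by_quantile(small_windows, small_world["mutations"],
                                      values, k=4)
        sizes = [len(groups.site_indices[lab]) for lab in groups.labels]
        assert max(sizes) - min(sizes) <= 1
        union = np.sort(np.concatenate(list(groups.site_indices.values())))
        assert np.array_equal(union, np.arange(small_windows.n_sites))

    def test_eight_values_four_groups(self):
        sites = [GenomicInterval("c", 100 + i * 3000, 200 + i * 3000,
                                 summit=150 + i * 3000) for i in range(8)]
        w = build_analysis_windows(sites, flank=1000)
        muts = mutation_table([("c", 150, "C", "T", "D1", "SNV")])
        groups = stratify_by_quantile(w, muts, np.arange(1.0, 9.0), k=4)
        expected = [[0, 1], [2, 3], [4, 5], [6, 7]]
        got = [sorted(groups.site_indices[lab]) for lab in groups.labels]
        assert got == expected

    def test_tied_values_fall_back_with_warning(self, small_world, small_windows):
        with pytest.warns(UserWarning, match="tied"):
            groups = stratify_by_quantile(
                small_windows, small_world["mutations"],
                np.ones(small_windows.n_sites), k=4,
            )
        sizes = [len(groups.site_indices[lab]) for lab in groups.labels]
        assert sum(sizes) == small_windows.n_sites

    def test_planted_intensity_effect_yields_high_pearson_r(self):
        # core rate proportional to intensity at n=2000 sites
        rng = np.random.default_rng(12)
        n = 2000
        sites = [GenomicInterval("c", 500 + i * 2500, 900 + i * 2500,
                                 summit=700 + i * 2500) for i in range(n)]
        w = build_analysis_windows(sites, flank=1000)
        intensity = rng.lognormal(1.0, 0.5, size=n)
        rows = []
        for i in range(n):
            lam = 0.8 * intensity[i] / intensity.mean()
            for _ in range(rng.poisson(lam)):
                pos = int(w.summits[i] + rng.integers(-200, 201))
                rows.append(("c", pos, "C", "T", f"D{rng.integers(10)}", "SNV"))
        groups = stratify_by_quantile(w, mutation_table(rows), intensity, k=4)
        assert groups.extra["pearson_r"] > 0.9

    def test_k_exceeding_sites_is_an_error(self, small_world, small_windows):
        with pytest.raises(ValueError):
            stratify_by_quantile(small_windows, small_world["mutations"],
                                 np.ones(small_windows.n_sites),
                                 k=small_windows.n_sites + 1)


class TestStratifyBySharing:
    def test_default_class_edges(self, small_world, small_windows):
        sharing = small_world["truth"].sites["sharing_count"].to_numpy()
        groups = stratify_by_sharing(small_windows, small_world["mutations"], sharing)
        for label, lo, hi in (("patient_specific", 1, 1), ("shared_2_3", 2, 3),
                              ("shared_gt3", 4, np.inf)):
            if label in groups.site_indices:
                vals = sharing[groups.site_indices[label]]
                assert np.all((vals >= lo) & (vals <= hi))

    def test_monotone_fold_change_with_intensity_coupled_sharing(
        self, small_world, small_windows
    ):
        # sharing correlates with intensity, and the planted factor grows with
        # intensity, so FC should increase across sharing classes
        sharing = small_world["truth"].sites["sharing_count"].to_numpy()
        edges = (("low", 1, 10), ("high", 11, np.inf))
        groups = stratify_by_sharing(small_windows, small_world["mutations"],
                                     sharing, classes=edges)
        assert (groups.results["high"].fold_change
                > groups.results["low"].fold_change)


class TestOutcomeBurden:
    def test_identical_groups_near_null(self, small_world, small_windows):
        win = small_windows.subset(np.arange(200))
        res = outcome_burden_test({"a": win, "b": win}, small_world["mutations"],
                                  n_sample=100, n_reps=30, seed=0)
        assert res["p"].iloc[0] > 0.05

    def test_planted_double_burden_detected(self):
        rng = np.random.default_rng(1)
        sites = [GenomicInterval("c", 500 + i * 3000, 900 + i * 3000,
                                 summit=700 + i * 3000) for i in range(300)]
        w = build_analysis_windows(sites, flank=1000)
        rows = []
        for i in range(300):
            lam = 2.0 if i >= 150 else 1.0
            for _ in range(rng.poisson(lam)):
                pos = int(w.summits[i] + rng.integers(-200, 201))
                rows.append(("c", pos, "C", "T", f"D{rng.integers(10)}", "SNV"))
        muts = mutation_table(rows)
        groups = {"good": w.subset(np.arange(150)),
                  "poor": w.subset(np.arange(150, 300))}
        res = outcome_burden_test(groups, muts, n_sample=100, n_reps=50, seed=2)
        assert res["p"].iloc[0] < 0.01
        assert res["mean_b"].iloc[0] > res["mean_a"].iloc[0]

    def test_single_rep_is_an_error(self, small_world, small_windows):
        with pytest.raises(ValueError):
            outcome_burden_test({"a": small_windows}, small_world["mutations"],
                                n_sample=10, n_reps=1)

    def test_small_group_is_an_error(self, small_world, small_windows):
        win = small_windows.subset(np.arange(5))
        with pytest.raises(ValueError, match="fewer"):
            outcome_burden_test({"a": win}, small_world["mutations"],
                                n_sample=100, n_reps=5)


class TestRankSites:
    def test_recurrent_flag_requires_exact_allele_match(self):
        sites = [GenomicInterval("c", 500, 900, summit=700)]
        w = build_analysis_windows(sites, flank=1000)
        rows = [
            ("c", 700, "C", "T", "D1", "SNV"),
            ("c", 700, "C", "T", "D2", "SNV"),
            ("c", 710, "G", "A", "D1", "SNV"),
        ]
        res = rank_sites_by_burden(w, mutation_table(rows))
        assert res.iloc[0]["n_mutations"] == 3
        assert res.iloc[0]["n_donors"] == 2
        assert bool(res.iloc[0]["has_recurrent"])
        # same position, different alt: not recurrent
        rows2 = [("c", 700, "C", "T", "D1", "SNV"), ("c", 700, "C", "G", "D2", "SNV")]
        res2 = rank_sites_by_burden(w, mutation_table(rows2))
        assert not bool(res2.iloc[0]["has_recurrent"])

    def test_ranking_matches_sort_oracle(self, small_world, small_windows):
        res = rank_sites_by_burden(small_windows, small_world["mutations"])
        counts = core_mutation_counts(small_windows, small_world["mutations"])
        assert np.array_equal(res["n_mutations"].to_numpy(),
                              np.sort(counts)[::-1])


class TestStratifyByLabel:
    def test_groups_partition_sites(self, small_world, small_windows):
        outcome = small_world["truth"].sites["outcome"].to_numpy()
        groups = stratify_by_label(small_windows, small_world["mutations"],
                                   outcome, key="outcome_class")
        total = sum(len(v) for v in groups.site_indices.values())
        assert total == small_windows.n_sites
        qs = [groups.results[lab].q_value for lab in groups.labels]
        ps = [groups.results[lab].p_value for lab in groups.labels]
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
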