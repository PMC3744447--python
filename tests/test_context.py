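"""Gene grouping, genomic context, enrichment statistics and TSS profiles."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom, rankdata

from sinefactory.context import (
    ExpressionRecord,
    GeneRecord,
    RepeatElement,
    SineProfileConfig,
    acetylated_sines,
    classify_genes,
    classify_region_context,
    classify_regions_context,
    fisher_2x2,
    mannwhitney,
    repeat_enrichment,
    sample_background,
    sine_density_profile,
    sine_profile_matrix,
    tss_profile_matrix,
    tss_window_stats,
)
from sinefactory.windowscan import DifferentialRegion

from conftest import make_library


def fisher_oracle(table):
    """Full hypergeometric enumeration: sum of P(tables at least as extreme)."""
    (a, b), (c, d) = table
    n1, n0, k = a + b, c + d, a + c
    support = range(max(0, k - n0), min(n1, k) + 1)
    p_obs = hypergeom.pmf(a, n1 + n0, n1, k)
    return sum(
        hypergeom.pmf(x, n1 + n0, n1, k)
        for x in support
        if hypergeom.pmf(x, n1 + n0, n1, k) <= p_obs * (1 + 1e-9)
    )


def mw_oracle(x, y, alternative="two-sided"):
    """Independent enumeration oracle using midrank U over all assignments."""
    x, y = list(x), list(y)
    nx = len(x)
    pooled = np.array(x + y, float)

    def u_of(idx):
        ranks = rankdata(pooled)
        rx = ranks[list(idx)].sum()
        return rx - nx * (nx + 1) / 2.0

    u_obs = u_of(range(nx))
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        u = u_of(idx)
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p_le, p_ge = le / total, ge / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_le, p_ge))


def expr(gid, dc, ds, fold, p):
    return ExpressionRecord(gid, dc, ds, fold, p)


class TestClassifyGenes:
    def test_reference_cases(self):
        records = [
            expr("silent", False, False, 1.0, 1.0),  # CS
            expr("induced", True, True, 1.30, 0.01),  # NI
            expr("edge", True, True, 1.24, 0.01),  # inclusive threshold -> NI
            expr("repressed", True, True, 1 / 1.5, 0.01),  # NR
            expr("stable", True, True, 1.02, 0.8),  # CE
            expr("weak", True, True, 1.50, 0.20),  # fold without p -> CE
        ]
        groups = classify_genes(records)
        assert groups == {
            "silent": "CS", "induced": "NI", "edge": "NI",
            "repressed": "NR", "stable": "CE", "weak": "CE",
        }

    def test_half_detected_gene_is_unassigned_with_warning(self):
        with pytest.warns(UserWarning, match="unassigned"):
            groups = classify_genes([expr("half", True, False, 1.05, 0.9)])
        assert groups["half"] == "unassigned"

    def test_duplicate_gene_rejected(self):
        records = [expr("g", True, True, 1.0, 1.0)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            classify_genes(records)


def gene(gid, chrom, strand, tss, body, group="unassigned"):
    return GeneRecord(gid, chrom, strand, tss, body, group)


class TestRegionContext:
    genes = [
        gene("g1", "chr1", "+", 5000, (5000, 9000)),
        gene("g2", "chr1", "-", 19_999, (12_000, 20_000)),
    ]

    def test_tss_takes_precedence_over_gene_body(self):
        r = DifferentialRegion("chr1", 4000, 6000, "+dAc", 5.0, 1)
        assert classify_region_context(r, self.genes) == "TSS"

    def test_intronic_region_is_gene_body(self):
        r = DifferentialRegion("chr1", 6000, 8000, "+dAc", 5.0, 1)
        assert classify_region_context(r, self.genes) == "gene_body"

    def test_gene_free_region_is_extragenic(self):
        r = DifferentialRegion("chr2", 0, 2000, "+dAc", 5.0, 1)
        assert classify_region_context(r, self.genes) == "extragenic"

    def test_classification_partitions_regions(self, rng):
        regions = [
            DifferentialRegion("chr1", int(s), int(s) + 2000, "+dAc", 5.0, 1)
            for s in rng.integers(0, 30_000, 40)
        ]
        labels = classify_regions_context(regions, self.genes)
        assert len(labels) == len(regions)
        assert labels.value_counts().sum() == len(regions)
        for r, lab in zip(regions, labels):
            assert lab == classify_region_context(r, self.genes)


class TestFisher:
    def test_worked_value_2_0_0_2(self):
        assert fisher_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)

    def test_matches_enumeration_oracle_all_small_tables(self):
        for total in range(1, 13):
            for a in range(total + 1):
                for b in range(total - a + 1):
                    for c in range(total - a - b + 1):
                        d = total - a - b - c
                        table = [[a, b], [c, d]]
                        if a + b == 0 or c + d == 0:
                            continue
                        assert fisher_2x2(table) == pytest.approx(
                            fisher_oracle(table), abs=1e-9
                        ), table


class TestMannWhitney:
    def test_worked_separated_samples(self):
        assert mannwhitney([1, 2, 3], [11, 12, 13], "less") == pytest.approx(0.05)
        assert mannwhitney([1, 2, 3], [11, 12, 13]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert mannwhitney([1, 2, 3], [1, 2, 3]) == 1.0
        assert mannwhitney([0, 0, 0], [0, 0, 0]) == 1.0

    def test_matches_enumeration_oracle_small_samples_with_ties(self, rng):
        for _ in range(40):
            nx = int(rng.integers(1, 7))
            ny = int(rng.integers(1, 13 - nx))
            x = rng.integers(0, 4, nx).tolist()
            y = rng.integers(0, 4, ny).tolist()
            for alt in ("two-sided", "greater", "less"):
                assert mannwhitney(x, y, alt) == pytest.approx(
                    mw_oracle(x, y, alt), abs=1e-9
                ), (x, y, alt)

    def test_normal_approximation_close_to_exact_at_crossover(self, rng):
        x = rng.normal(0, 1, 10).tolist()
        y = rng.normal(1, 1, 10).tolist()
        exact = mannwhitney(x, y, exact_max_n=20)
        approx = mannwhitney(x, y, exact_max_n=0)
        assert approx == pytest.approx(exact, abs=0.02)


class TestRepeatEnrichment:
    repeats = [
        RepeatElement("chr1", 100, 250, "+", "B1_Mus1", "Alu/B1", "SINE"),
        RepeatElement("chr1", 5100, 5250, "+", "B2_Mm1t", "B2", "SINE"),
        RepeatElement("chr1", 9100, 9200, "-", "L1Md", "L1", "LINE"),
    ]

    def test_identical_sets_give_null_result(self):
        regions = [("chr1", 0, 2000), ("chr1", 5000, 7000)]
        table = repeat_enrichment(regions, self.repeats, regions)
        assert (table["odds_ratio"] == 1.0).all() or (table["n_regions"] == table["n_background"]).all()
        assert (table["fisher_p"] == 1.0).all()

    def test_absent_family_zero_frequency_p_one(self):
        regions = [("chr2", 0, 2000)]
        bg = [("chr2", 5000, 7000)]
        table = repeat_enrichment(regions, self.repeats, bg, by="family")
        assert (table["freq_per_1000_regions"] == 0).all()
        assert (table["fisher_p"] == 1.0).all()

    def test_frequency_per_1000_units(self):
        regions = [("chr1", 0, 2000), ("chr1", 4000, 6000), ("chr2", 0, 2000)]
        bg = [("chr2", 10, 2010)] * 3
        table = repeat_enrichment(regions, self.repeats, bg, by="class").set_index("class")
        assert table.loc["SINE", "n_regions"] == 2
        assert table.loc["SINE", "freq_per_1000_regions"] == pytest.approx(2000 / 3)

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            repeat_enrichment([], self.repeats, [("chr1", 0, 10)])


class TestSampleBackground:
    def test_seed_reproducibility_and_width_multiset(self):
        sizes = {"chr1": 100_000, "chr2": 50_000}
        widths = [2000, 3000, 2000, 5500]
        a = sample_background(sizes, widths, rng=42)
        b = sample_background(sizes, widths, rng=42)
        assert a == b
        assert sorted(e - s for _, s, e in a) == sorted(widths)
        for chrom, s, e in a:
            assert 0 <= s < e <= sizes[chrom]

    def test_tss_constraint_every_interval_covers_a_tss(self):
        sizes = {"chr1": 100_000}
        tss = [("chr1", p) for p in (10_000, 40_000, 41_000, 90_000)]
        ivs = sample_background(sizes, [2000] * 25, constraint="tss_overlapping", tss=tss, rng=3)
        for chrom, s, e in ivs:
            assert any(c == chrom and s <= p < e for c, p in tss)

    def test_unsatisfiable_constraint_rejected(self):
        with pytest.raises(ValueError):
            sample_background({"chr1": 1000}, [2000], constraint="tss_overlapping",
                              tss=[("chr1", 10)], rng=0)


class TestTssProfiles:
    sizes = {"chr1": 100_000}

    def test_no_tags_zero_profile(self):
        lib = make_library("x", self.sizes, {})
        g = [gene("g", "chr1", "+", 50_000, (50_000, 60_000))]
        offsets, mat = tss_profile_matrix(lib, g)
        assert np.asarray(mat.filled(0)).sum() == 0

    def test_plus_strand_binning(self):
        lib = make_library("x", self.sizes, {"chr1": [(50_150, "+")]})
        g = [gene("g", "chr1", "+", 50_000, (50_000, 60_000))]
        offsets, mat = tss_profile_matrix(lib, g)
        j = list(offsets).index(100)
        assert mat[0, j] == 1 and np.asarray(mat).sum() == 1

    def test_minus_strand_coordinate_flip(self):
        lib = make_library("x", self.sizes, {"chr1": [(49_850, "+")]})
        g = [gene("g", "chr1", "-", 50_000, (40_001, 50_001))]
        offsets, mat = tss_profile_matrix(lib, g)
        j = list(offsets).index(100)  # genomic TSS-150 -> oriented bin [+100,+200)
        assert mat[0, j] == 1 and np.asarray(mat).sum() == 1

    def test_edge_gene_bins_masked(self):
        lib = make_library("x", self.sizes, {})
        g = [gene("g", "chr1", "+", 500, (500, 4000))]
        offsets, mat = tss_profile_matrix(lib, g, extent=2000)
        assert mat.mask[0, list(offsets).index(-2000)]
        assert not mat.mask[0, list(offsets).index(0)]

    def test_strand_symmetry_under_reflection(self, rng):
        # reflecting tags and annotations through the chromosome midpoint and
        # flipping strands leaves TSS-relative profiles unchanged
        L = self.sizes["chr1"]
        pos = rng.integers(40_000, 60_000, 200)
        lib = make_library("x", self.sizes, {"chr1": [(int(p), "+") for p in pos]})
        lib_r = make_library(
            "xr", self.sizes, {"chr1": [(int(L - 1 - p), "-") for p in pos]}
        )
        g_fwd = [gene("g", "chr1", "+", 50_000, (50_000, 60_000))]
        g_rev = [gene("g", "chr1", "-", L - 1 - 50_000, (L - 1 - 60_000 + 1, L - 50_000))]
        _, m1 = tss_profile_matrix(lib, g_fwd)
        _, m2 = tss_profile_matrix(lib_r, g_rev)
        np.testing.assert_array_equal(np.asarray(m1), np.asarray(m2))

    def test_window_stats_summary_and_tests(self):
        vals = {"CE": np.array([1.0, 2, 3, 4, 5]), "CS": np.array([0.0, 0, 1, 1, 2])}
        summary, tests = tss_window_stats(vals, pairs=[("CE", "CS")])
        row = summary.set_index("group").loc["CE"]
        assert row["min"] == 1 and row["max"] == 5 and row["median"] == 3
        p = tests.iloc[0]["mw_p"]
        assert p == pytest.approx(mw_oracle(vals["CE"], vals["CS"]), abs=1e-9)

    def test_single_gene_group_summary_without_test(self):
        summary, tests = tss_window_stats({"NI": np.array([2.0]), "CE": np.array([1.0, 2.0])})
        assert set(summary["group"]) == {"NI", "CE"}
        assert len(tests) == 0


def sine(chrom, start, end):
    return RepeatElement(chrom, start, end, "+", "B1_Mus1", "Alu/B1", "SINE")


class TestAcetylatedSines:
    plus = [DifferentialRegion("chr1", 10_000, 14_000, "+dAc", 5.0, 2)]

    def test_contained_sine_flagged(self):
        assert acetylated_sines(self.plus, [sine("chr1", 11_000, 11_150)])

    def test_abutting_sine_not_flagged(self):
        assert acetylated_sines(self.plus, [sine("chr1", 14_000, 14_150)]) == []
        assert acetylated_sines(self.plus, [sine("chr1", 9_850, 10_000)]) == []

    def test_line_inside_region_not_returned(self):
        line = RepeatElement("chr1", 11_000, 11_500, "+", "L1Md", "L1", "LINE")
        assert acetylated_sines(self.plus, [line]) == []


class TestSineDensityProfile:
    sizes = {"chr1": 10_000_000}

    def test_no_sines_zero_profile(self):
        g = {"NI": [gene("g", "chr1", "+", 5_000_000, (5_000_000, 5_020_000))]}
        out = sine_density_profile([], g, self.sizes)
        assert (out["mean_NI"].fillna(0) == 0).all()

    def test_single_sine_contributes_to_expected_offset_range(self):
        # midpoint at +30,000 under the centred closed-window convention
        tss = 5_000_000
        g = [gene("g", "chr1", "+", tss, (tss, tss + 20_000))]
        s = [sine("chr1", tss + 30_000 - 75, tss + 30_000 + 75)]
        offsets, mat = sine_profile_matrix(s, g, self.sizes)
        hit = [int(o) for o, v in zip(offsets, np.asarray(mat)[0]) if v > 0]
        assert hit == list(range(5_000, 55_001, 5_000))

    def test_minus_strand_orientation(self):
        tss = 5_000_000
        g = [gene("g", "chr1", "-", tss, (tss - 19_999, tss + 1))]
        s = [sine("chr1", tss - 30_000 - 75, tss - 30_000 + 75)]  # downstream for '-'
        offsets, mat = sine_profile_matrix(s, g, self.sizes)
        hit = [int(o) for o, v in zip(offsets, np.asarray(mat)[0]) if v > 0]
        assert hit == list(range(5_000, 55_001, 5_000))

    def test_group_mean_equals_mean_of_per_gene_profiles(self, rng):
        tsss = [1_000_000, 3_000_000, 6_000_000]
        genes = [gene(f"g{i}", "chr1", "+", t, (t, t + 20_000)) for i, t in enumerate(tsss)]
        sines = []
        for t in tsss:
            for off in rng.integers(-90_000, 90_000, 5):
                sines.append(sine("chr1", t + int(off) - 75, t + int(off) + 75))
        out = sine_density_profile(sines, {"NI": genes}, self.sizes)
        per_gene = [
            np.asarray(sine_profile_matrix(sines, [g], self.sizes)[1])[0] for g in genes
        ]
        np.testing.assert_allclose(out["mean_NI"], np.mean(per_gene, axis=0))

    def test_edge_gene_offsets_masked(self):
        g = [gene("g", "chr1", "+", 50_000, (50_000, 70_000))]
        out = sine_density_profile([], {"NI": g}, self.sizes)
        assert math.isnan(out.set_index("offset").loc[-100_000, "mean_NI"])
        assert out.set_index("offset").loc[100_000, "n_NI"] == 1
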