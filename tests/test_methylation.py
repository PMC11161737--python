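import itertools
import math

import numpy as np
import pandas as pd
import pytest

from extremoscope.core_data import GeneAnnotation, SampleAnnotation
from extremoscope.methylation import (
    BetaMatrix,
    benjamini_hochberg,
    cimp_enrichment,
    compare_context_distribution,
    map_cpgs_to_promoters,
    segment_cgi_regions,
    test_promoter_association as promoter_association,
    wilcoxon_rank_sum,
)
from extremoscope.outliers import OutlierAtlas
from extremoscope.simulate import make_gene_annotation, simulate_methylation


def brute_force_region(pos, islands):
    """Per-base oracle: smallest distance to any island decides the class."""
    best = None
    for s, e in islands:
        if s <= pos < e:
            d = 0
        elif pos < s:
            d = s - pos
        else:
            d = pos - e + 1
        best = d if best is None else min(best, d)
    if best is None:
        return "open_sea"
    if best == 0:
        return "island"
    if best <= 2000:
        return "shore"
    if best <= 4000:
        return "shelf"
    return "open_sea"


class TestCgiSegmentation:
    def test_single_island_flanks(self):
        seg = segment_cgi_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [10000], "end": [11000]})
        )
        assert seg.classify("chr1", 10500) == "island"
        assert seg.classify("chr1", 9500) == "shore"
        assert seg.classify("chr1", 8000) == "shore"
        assert seg.classify("chr1", 7999) == "shelf"
        assert seg.classify("chr1", 12999) == "shore"
        assert seg.classify("chr1", 13000) == "shelf"
        assert seg.classify("chr1", 14999) == "shelf"
        assert seg.classify("chr1", 15000) == "open_sea"

    def test_close_islands_gap_is_all_shore(self):
        # two islands 3 kb apart: every gap base within 2 kb of an island
        seg = segment_cgi_regions(
            pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [10000, 14000],
                          "end": [11000, 15000]})
        )
        gap = np.arange(11000, 14000)
        classes = set(seg.classify_many("chr1", gap))
        assert classes == {"shore"}

    def test_partition_matches_per_base_oracle(self):
        islands = [(3000, 4000), (5500, 6000), (20000, 21000)]
        seg = segment_cgi_regions(
            pd.DataFrame(
                {"chrom": "chrT", "start": [s for s, _ in islands],
                 "end": [e for _, e in islands]}
            )
        )
        pos = np.arange(0, 30000, 7)  # samples the whole toy chromosome
        got = seg.classify_many("chrT", pos)
        expected = [brute_force_region(p, islands) for p in pos]
        assert list(got) == expected

    def test_unknown_chromosome_is_open_sea(self):
        seg = segment_cgi_regions(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]})
        )
        assert seg.classify("chr9", 5) == "open_sea"


class TestPromoterMapping:
    @pytest.fixture
    def ann(self):
        df = pd.DataFrame(
            {
                "symbol": ["P", "M", "E"],
                "chromosome": ["chr1", "chr1", "chr2"],
                "strand": ["+", "-", "+"],
                "tss_list": [(5000,), (5000,), ()],
                "biotype": ["protein_coding"] * 3,
                "par_y": [False] * 3,
            },
            index=pd.Index(["gp", "gm", "ge"], name="gene_id"),
        )
        return GeneAnnotation(df)

    def test_strand_aware_windows(self, ann):
        manifest = pd.DataFrame(
            {"chrom": ["chr1"] * 4, "pos": [4000, 4999, 6000, 5000]},
            index=pd.Index(["c_up", "c_attss", "c_down", "c_plus1"], name="cpg_id"),
        )
        ctx = map_cpgs_to_promoters(manifest, ann)
        plus = set(ctx[ctx.gene_id == "gp"]["cpg_id"])
        minus = set(ctx[ctx.gene_id == "gm"]["cpg_id"])
        # + strand: upstream window only, TSS position itself excluded
        assert plus == {"c_up"}
        # − strand: mirror image downstream in coordinates
        assert minus == {"c_down", "c_plus1"}

    def test_mirrored_toy_genome_maps_same_cpgs(self, ann):
        # distance of mapped CpGs from TSS identical on both strands
        manifest = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "pos": [4999 - 700, 4999 + 700]},
            index=pd.Index(["c_plus", "c_minus"], name="cpg_id"),
        )
        ctx = map_cpgs_to_promoters(manifest, ann)
        assert set(ctx[ctx.gene_id == "gp"]["cpg_id"]) == {"c_plus"}
        assert set(ctx[ctx.gene_id == "gm"]["cpg_id"]) == {"c_minus"}

    def test_gene_without_tss_skipped(self, ann):
        manifest = pd.DataFrame(
            {"chrom": ["chr2"], "pos": [4000]},
            index=pd.Index(["c"], name="cpg_id"),
        )
        ctx = map_cpgs_to_promoters(manifest, ann)
        assert "ge" not in set(ctx["gene_id"])


def rank_sum_enumeration_p(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    obs = sum(1 for x in a for y in b if x > y)
    stat_obs = min(obs, n * m - obs)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        u = sum(
            1
            for i in combo
            for j in range(n + m)
            if j not in combo and pooled[i] > pooled[j]
        )
        if min(u, n * m - u) <= stat_obs:
            count += 1
        total += 1
    return count / total


class TestWilcoxon:
    def test_identical_constant_vectors(self):
        assert wilcoxon_rank_sum([0.5] * 4, [0.5] * 6) == 1.0

    def test_exact_small_case(self):
        p = wilcoxon_rank_sum([0.9, 0.95], [0.10, 0.12, 0.15])
        assert p == pytest.approx(0.2, abs=1e-12)  # 2 / C(5,2)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(60):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 7))
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            assert wilcoxon_rank_sum(a, b) == pytest.approx(
                rank_sum_enumeration_p(a, b), abs=1e-8
            )

    def test_missing_values_dropped(self):
        p = wilcoxon_rank_sum([0.9, np.nan, 0.95], [0.10, 0.12, 0.15, np.nan])
        assert p == pytest.approx(0.2, abs=1e-12)


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )
        assert np.allclose(benjamini_hochberg([0.005, 0.5]), [0.01, 0.5])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    def test_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        fdr = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()
        perm = rng.permutation(40)
        assert np.allclose(benjamini_hochberg(p[perm]), fdr[perm])
        assert (fdr <= 1.0).all()


def atlas_for(gene_outliers, direction="negative"):
    rows = []
    for g, ss in gene_outliers.items():
        for s in ss:
            rows.append(
                dict(gene_id=g, symbol=g, sample_id=s, direction=direction,
                     stage="extreme", fpkm=0.1, median_fpkm=20.0, log2fc=-4.2)
            )
    return OutlierAtlas(pd.DataFrame(rows))


class TestPromoterAssociation:
    @pytest.fixture
    def planted(self):
        samples = [f"CL{i:04d}" for i in range(1, 101)]
        genes = [f"ENSG9{i:08d}" for i in range(1, 13)]
        ann = make_gene_annotation(genes)
        rng = np.random.default_rng(0)
        silenced = {g: list(rng.choice(samples, 4, replace=False)) for g in genes[:4]}
        beta, manifest, cgi, _ = simulate_methylation(ann, silenced, samples, seed=3)
        ctx = map_cpgs_to_promoters(manifest, ann,
                                    segmentation=segment_cgi_regions(cgi))
        return samples, ann, silenced, beta, ctx

    def test_planted_silenced_genes_flagged(self, planted):
        samples, ann, silenced, beta, ctx = planted
        atlas = atlas_for(silenced)
        assoc = promoter_association(atlas, beta, ctx)
        sig = assoc[assoc.significant]
        assert set(sig.gene_id) == set(silenced)
        assert (sig.fdr < 0.05).all()
        assert (sig.median_beta_outliers > 0.8).all()
        assert (sig.median_beta_others < 0.2).all()

    def test_single_outlier_gene_not_tested(self, planted):
        samples, ann, silenced, beta, ctx = planted
        g = next(iter(silenced))
        atlas = atlas_for({g: silenced[g][:1]})
        assoc = promoter_association(atlas, beta, ctx)
        assert len(assoc) == 0

    def test_median_rule_required_beyond_fdr(self, planted):
        """A strong shift that stays below the 0.80/0.20 medians must not
        be declared significant."""
        samples, ann, silenced, beta, ctx = planted
        g = next(iter(silenced))
        shifted = beta.values.copy()
        # compress the planted gene's CpGs toward 0.6: tiny p, rule fails
        gene_cpgs = ctx[ctx.gene_id == g]["cpg_id"]
        shifted.loc[gene_cpgs] = shifted.loc[gene_cpgs].clip(upper=0.6)
        assoc = promoter_association(
            atlas_for({g: silenced[g]}), BetaMatrix(shifted), ctx
        )
        assert (assoc.fdr < 0.05).any()
        assert not assoc.significant.any()

    def test_methods_rule_direction_swaps_assignment(self, planted):
        samples, ann, silenced, beta, ctx = planted
        atlas = atlas_for(silenced)  # negative outliers, hypermethylated
        assoc = promoter_association(
            atlas, beta, ctx, beta_rule_direction="methods"
        )
        # under the swapped convention these same genes no longer qualify
        assert not assoc.significant.any()


class TestContextDistribution:
    def test_perfect_separation_chi_square(self):
        assoc = pd.DataFrame(
            {
                "significant": [True] * 10 + [False] * 10,
                "region_class": ["island"] * 10 + ["open_sea"] * 10,
            }
        )
        _, chi2, p = compare_context_distribution(assoc)
        assert chi2 == pytest.approx(20.0)

    def test_identical_distribution_statistic_zero(self):
        assoc = pd.DataFrame(
            {
                "significant": [True, True, False, False],
                "region_class": ["island", "shore", "island", "shore"],
            }
        )
        _, chi2, _ = compare_context_distribution(assoc)
        assert chi2 == pytest.approx(0.0)

    def test_degenerate_table_missing_statistic(self):
        assoc = pd.DataFrame(
            {"significant": [True, True], "region_class": ["island", "island"]}
        )
        _, chi2, p = compare_context_distribution(assoc)
        assert np.isnan(chi2)


def hypergeom_upper_tail_oracle(obs, N, K, n):
    """Closed-form upper tail from binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, k) * math.comb(N - K, n - k)
        for k in range(obs, min(K, n) + 1)
    ) / total


class TestCimpEnrichment:
    @pytest.fixture
    def cohort(self):
        samples = [f"s{i}" for i in range(10)]
        cimp = ["CIMP-H"] * 2 + ["CIMP-L"] * 2 + ["CIMP3"] * 3 + ["CIMP4"] * 3
        sa = SampleAnnotation(
            pd.DataFrame(
                {"cimp_class": cimp, "msi_status": ["MSS"] * 10},
                index=pd.Index(samples, name="sample_id"),
            )
        )
        return samples, sa

    def test_exact_small_population(self, cohort):
        samples, sa = cohort
        atlas = atlas_for({"g1": samples[:3]})  # all 3 outliers CIMP-positive
        res = cimp_enrichment(atlas, sa)
        assert res.iloc[0]["p_value"] == pytest.approx(4 / 120, abs=1e-12)
        assert res.iloc[0]["n_outliers_cimp_positive"] == 3

    def test_zero_positive_outliers_p_one(self, cohort):
        samples, sa = cohort
        atlas = atlas_for({"g1": samples[4:7]})  # none CIMP-positive
        res = cimp_enrichment(atlas, sa)
        assert res.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_matches_combinatorial_oracle(self, cohort):
        from scipy import stats

        rng = np.random.default_rng(3)
        for _ in range(100):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            obs = int(rng.integers(0, min(K, n) + 1))
            assert stats.hypergeom.sf(obs - 1, N, K, n) == pytest.approx(
                hypergeom_upper_tail_oracle(obs, N, K, n), abs=1e-10
            )

    def test_no_labels_rejected(self):
        sa = SampleAnnotation(
            pd.DataFrame(
                {"cimp_class": ["NA", "NA"], "msi_status": ["MSS", "MSS"]},
                index=pd.Index(["s0", "s1"], name="sample_id"),
            )
        )
        with pytest.raises(ValueError):
            cimp_enrichment(atlas_for({"g": ["s0", "s1"]}), sa)
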