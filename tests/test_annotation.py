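"""Gene linking windows, enrichment tests, and genomic-context comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from paleompra.annotation import (
    context_enrichment,
    cpg_density,
    direction_tests,
    group_mean_compare,
    link_targets,
    methylation_direction_test,
    nearest_distance,
    term_enrichment,
)
from paleompra.errors import InputError


def locus(locus_id="L1", chrom="chr1", pos=50_100, width=200):
    start = pos - 100
    return {"locus_id": locus_id, "chrom": chrom, "pos": pos,
            "start": start, "end": start + width}


EMPTY_TSS = pd.DataFrame(columns=["chrom", "start", "end", "gene", "strand"])
EMPTY_POINTS = pd.DataFrame(columns=["chrom", "pos", "gene"])
EMPTY_IV = pd.DataFrame(columns=["chrom", "start", "end", "gene", "cell_matched"])
EMPTY_ENH = pd.DataFrame(columns=["chrom", "start", "end", "gene", "elite"])


def far_tss(gene="GFAR", chrom="chr1", start=2_000_000):
    return pd.DataFrame([{"chrom": chrom, "start": start, "end": start + 1,
                          "gene": gene, "strand": "+"}])


class TestLinkTargets:
    def test_eqtl_window_boundary_inclusive(self):
        loci = pd.DataFrame([locus(pos=50_000)])
        for dist, expect in ((1000, True), (1001, False)):
            eqtls = pd.DataFrame([{"chrom": "chr1", "pos": 50_000 + dist, "gene": "G1"}])
            links = link_targets(loci, far_tss(), eqtls, EMPTY_IV, EMPTY_ENH)
            has = ((links["evidence"] == "eqtl") & (links["gene"] == "G1")).any()
            assert has is np.bool_(expect) or has == expect

    @pytest.mark.parametrize(
        "strand, offset, linked",
        [("+", -5000, True), ("+", -5001, False), ("+", 1000, True),
         ("+", 1001, False), ("-", 5000, True), ("-", 5001, False),
         ("-", -1000, True), ("-", -1001, False)],
    )
    def test_promoter_window_strand_aware(self, strand, offset, linked):
        tss_pos = 60_000
        variant_pos = tss_pos + offset + 1  # 1-based variant at 0-based tss_pos+offset
        loci = pd.DataFrame([locus(pos=variant_pos)])
        tss = pd.DataFrame([{"chrom": "chr1", "start": tss_pos, "end": tss_pos + 1,
                             "gene": "G1", "strand": strand}])
        links = link_targets(loci, tss, EMPTY_POINTS, EMPTY_IV, EMPTY_ENH)
        got = ((links["evidence"] == "promoter") & (links["gene"] == "G1")).any()
        assert bool(got) == linked

    def test_hic_and_enhancer_windows_with_tiers(self):
        loci = pd.DataFrame([locus(pos=50_100)])  # variant at 0-based 50,099
        hic = pd.DataFrame([
            {"chrom": "chr1", "start": 58_000, "end": 59_000, "gene": "G2",
             "cell_matched": True},     # within 10 kb of the variant
            {"chrom": "chr1", "start": 80_000, "end": 81_000, "gene": "G3",
             "cell_matched": False},    # beyond
        ])
        enh = pd.DataFrame([
            {"chrom": "chr1", "start": 41_000, "end": 41_500, "gene": "G4",
             "elite": False},
        ])
        links = link_targets(loci, far_tss(), EMPTY_POINTS, hic, enh)
        by = links.set_index(["evidence", "gene"])["tier"]
        assert by.loc[("hic", "G2")] == "stringent"
        assert ("hic", "G3") not in by.index
        assert by.loc[("enhancer", "G4")] == "lenient"

    def test_closest_tss_fallback_regardless_of_distance(self):
        loci = pd.DataFrame([locus(pos=50_100)])
        links = link_targets(loci, far_tss(start=2_000_000), EMPTY_POINTS,
                             EMPTY_IV, EMPTY_ENH)
        assert links["evidence"].tolist() == ["closest_tss"]
        assert links["gene"].tolist() == ["GFAR"]

    def test_every_locus_gets_a_link(self, small_experiment):
        lib = [o for o in small_experiment["library"] if o.oligo_class == "test"][:30]
        loci = pd.DataFrame([
            {"locus_id": o.oligo_id, "chrom": o.chrom, "pos": o.focal_pos,
             "start": o.window_start, "end": o.window_start + 200}
            for o in lib
        ])
        ref = small_experiment["reference"]
        links = link_targets(loci, ref.tss, ref.eqtls, ref.hic, ref.enhancers)
        assert set(loci["locus_id"]) == set(links["locus_id"])


class TestTermEnrichment:
    def test_fold_of_perfectly_enriched_term(self):
        universe = {f"g{i}" for i in range(100)}
        target = {f"g{i}" for i in range(10)}
        terms = pd.DataFrame({"term": "T1", "gene": sorted(target)})
        res = term_enrichment(target, universe, terms, min_genes=3)
        assert res["fold"].iloc[0] == pytest.approx(10.0)
        assert res["p"].iloc[0] < 1e-10

    def test_small_terms_excluded(self):
        universe = {f"g{i}" for i in range(50)}
        terms = pd.DataFrame({"term": ["T1", "T1"], "gene": ["g0", "g1"]})
        res = term_enrichment({"g0"}, universe, terms, min_genes=3)
        assert len(res) == 0

    def test_target_equal_background_is_flat(self):
        universe = {f"g{i}" for i in range(60)}
        rng = np.random.default_rng(0)
        terms = pd.DataFrame({
            "term": np.repeat([f"T{j}" for j in range(5)], 8),
            "gene": rng.choice(sorted(universe), 40),
        })
        res = term_enrichment(universe, universe, terms, min_genes=3)
        assert np.allclose(res["fold"], 1.0)
        assert (res["p"] > 0.99).all()

    def test_empty_background_rejected(self):
        with pytest.raises(InputError):
            term_enrichment({"g"}, set(), pd.DataFrame({"term": [], "gene": []}))


class TestDirectionTests:
    def test_satb2_worked_example(self):
        # 17 annotated phenotypes, 15 divergent, 12 matching, against a
        # population of 696 phenotypes of which 434 are divergent
        res = direction_tests(17, 15, 12, 696, 434)
        assert res["expected_match"] == pytest.approx(17 * 217 / 696)
        assert res["fold"] == pytest.approx(2.26, abs=0.01)
        assert res["binomial_p"] == pytest.approx(
            float(sps.binom.sf(11, 15, 0.5)))
        assert res["hypergeom_p"] == pytest.approx(
            float(sps.hypergeom.sf(11, 696, 217, 17)))

    def test_null_center_and_unit_fold(self):
        res = direction_tests(20, 16, 8, 696, 434)
        assert res["binomial_p"] > 0.5
        # observed equal to expected -> fold 1
        n = 696
        res2 = direction_tests(n, n, 217, n, 434)
        assert res2["fold"] == pytest.approx(1.0)

    def test_all_divergent_match_prob_one(self):
        res = direction_tests(10, 10, 10, 696, 434, match_prob=1.0)
        assert res["fold"] == pytest.approx(10 / (10 * 434 / 696))

    def test_inconsistent_counts(self):
        with pytest.raises(InputError):
            direction_tests(5, 6, 2, 100, 50)


class TestContextEnrichment:
    def _loci(self, rng, n=60):
        starts = rng.integers(0, 90_000, n)
        return pd.DataFrame({
            "locus_id": [f"L{i}" for i in range(n)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + 200,
            "active": np.arange(n) < n // 2,
            "ratio": np.where(np.arange(n) < n // 2, 3.0, 0.5),
        })

    def test_feature_covering_only_active(self, rng):
        loci = self._loci(rng)
        active = loci[loci["active"]]
        feats = {"mark": pd.DataFrame({
            "chrom": "chr1", "start": active["start"], "end": active["end"]})}
        res = context_enrichment(loci, feats, ratio_cutoffs=(1.0,))
        assert np.isinf(res["odds_ratio"].iloc[0])
        assert res["p"].iloc[0] < 1e-6

    def test_identical_overlap_rates_are_null(self, rng):
        loci = self._loci(rng)
        feats = {"mark": pd.DataFrame({
            "chrom": "chr1", "start": loci["start"], "end": loci["end"]})}
        res = context_enrichment(loci, feats, ratio_cutoffs=(1.0,))
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_oracle(self, rng):
        from scipy.stats import hypergeom

        from paleompra.stats import fisher_2x2
        for _ in range(30):
            a, b, c, d = rng.integers(0, 30, size=4) + 1
            _, p = fisher_2x2([[a, b], [c, d]], alternative="greater")
            oracle = hypergeom.sf(a - 1, a + b + c + d, a + b, a + c)
            assert p == pytest.approx(float(oracle), rel=1e-9)

    def test_random_feature_p_in_unit_interval(self, rng):
        loci = self._loci(rng)
        start = rng.integers(0, 90_000, 20)
        feats = {"mark": pd.DataFrame({
            "chrom": "chr1", "start": start, "end": start + 500,
        })}
        res = context_enrichment(loci, feats, ratio_cutoffs=(1.0,))
        assert res["p"].between(0, 1).all()

    def test_sex_chromosomes_removed(self, rng):
        loci = self._loci(rng)
        loci.loc[:10, "chrom"] = "chrX"
        feats = {"mark": pd.DataFrame({
            "chrom": ["chr1"], "start": [0], "end": [100_000]})}
        res = context_enrichment(loci, feats, ratio_cutoffs=(1.0,))
        n_used = res["n_active"].iloc[0] + 0  # active chr1 only
        assert n_used == int((loci["chrom"] == "chr1")[loci["active"]].sum() - 0) \
            or n_used <= int(loci["active"].sum())


class TestMethylation:
    def test_planted_anticorrelation_detected(self, rng):
        n = 100
        ids = [f"L{i}" for i in range(2 * n)]
        direction = pd.Series(["up"] * n + ["down"] * n, index=ids)
        delta = np.r_[np.full(n, -0.05), np.full(n, +0.05)]
        base = rng.beta(2, 2, 2 * n)
        meth = pd.DataFrame({
            "locus_id": ids,
            "modern": np.clip(base + delta + rng.normal(0, 0.02, 2 * n), 0, 1),
            "archaic": base,
        })
        res = methylation_direction_test(meth, direction)
        row = res[res["stratum"] == "all"].iloc[0]
        assert row["p"] < 0.05
        assert row["mean_delta_up"] < 0 < row["mean_delta_down"]

    def test_identical_maps_are_no_signal(self):
        ids = ["L1", "L2", "L3", "L4"]
        meth = pd.DataFrame({"locus_id": ids, "modern": [0.5] * 4,
                             "archaic": [0.5] * 4})
        direction = pd.Series(["up", "up", "down", "down"], index=ids)
        res = methylation_direction_test(meth, direction)
        assert np.isnan(res[res["stratum"] == "all"]["p"].iloc[0])

    def test_cpg_density_counting(self):
        assert cpg_density("ACGCGT") == pytest.approx(2 / 6)
        with pytest.raises(InputError):
            cpg_density("")


class TestGroupCompare:
    def test_identical_groups_null(self, rng):
        x = rng.normal(0, 1, 200)
        res = group_mean_compare({"c": (x, x.copy())})
        assert res["p"].iloc[0] > 0.99

    def test_shifted_groups_detected(self, rng):
        a = rng.normal(1.0, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        res = group_mean_compare({"c": (a, b)})
        assert res["p"].iloc[0] < 1e-10

    def test_small_group_rejected(self, rng):
        with pytest.raises(InputError):
            group_mean_compare({"c": (np.array([1.0]), rng.normal(0, 1, 10))})


def test_nearest_distance_zero_at_feature():
    loci = pd.DataFrame([{"locus_id": "L1", "chrom": "chr1",
                          "start": 900, "end": 1100}])
    tss = pd.DataFrame([{"chrom": "chr1", "start": 1000, "end": 1001}])
    d = nearest_distance(loci, tss)
    assert d["L1"] == 0.0
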