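"""Screening statistics, meta-analysis, selection, divergence, enrichment.

Every closed-form statistic is cross-checked against an independent
brute-force oracle (per-probe scipy.stats.pearsonr, direct formula
evaluation, exact hypergeometric summation) rather than the vectorized
implementation path.
"""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ooclock import (
    BetaMatrix,
    CpGAnnotation,
    ValidationError,
    classify_divergent,
    correlation_screen,
    cpgs_near_gene,
    cross_tissue_z_correlation,
    feature_enrichment,
    island_z_comparison,
    mean_methylation_by_island,
    meta_analysis,
    select_top_cpgs,
    stouffer_meta,
)
from ooclock.ewas import Z_MAX


def brute_force_screen(X, ages):
    """Independent per-probe oracle: scipy pearsonr + explicit formulas."""
    n = len(ages)
    rows = []
    for i in range(X.shape[0]):
        x = X[i]
        if np.ptp(x) == 0:
            rows.append((np.nan,) * 4)
            continue
        r, _ = stats.pearsonr(x, ages)
        t = r * math.sqrt(n - 2) / math.sqrt(1 - r**2) if abs(r) < 1 else math.inf
        p = 2 * stats.t.sf(abs(t), n - 2)
        p = max(p, 1e-300)
        z = math.copysign(1, r) * min(stats.norm.isf(p / 2), Z_MAX)
        rows.append((r, t, p, z))
    return np.array(rows)


class TestCorrelationScreen:
    def test_hand_example(self, beta_matrix, sample_table):
        # ages 1..5 against betas (2,1,4,3,5)/10: r = 0.8, t = 2.3094
        samples = sample_table(n=5, ages=[1, 2, 3, 4, 5])
        bm = beta_matrix(np.array([[0.2, 0.1, 0.4, 0.3, 0.5]]), samples=samples.sample_ids)
        ew = correlation_screen(bm, samples)
        assert ew["r"].iloc[0] == pytest.approx(0.8, abs=1e-12)
        assert ew["t"].iloc[0] == pytest.approx(0.8 * np.sqrt(3) / np.sqrt(0.36), abs=1e-10)
        expected_p = 2 * stats.t.sf(abs(ew["t"].iloc[0]), 3)
        assert ew["p"].iloc[0] == pytest.approx(expected_p, rel=1e-12)
        expected_z = stats.norm.isf(expected_p / 2)
        assert ew["z"].iloc[0] == pytest.approx(expected_z, rel=1e-12)

    def test_matches_brute_force_oracle(self, sample_table):
        rng = np.random.default_rng(12)
        n, p = 50, 200
        samples = sample_table(n=n, ages=rng.uniform(0.5, 13.3, n))
        X = np.clip(rng.uniform(0.2, 0.8, (p, 1)) + rng.normal(0, 0.05, (p, n)), 0, 1)
        bm = BetaMatrix(
            pd.DataFrame(X, index=[f"cg{i}" for i in range(p)], columns=samples.sample_ids)
        )
        ew = correlation_screen(bm, samples)
        oracle = brute_force_screen(X, samples.ages)
        np.testing.assert_allclose(ew["r"], oracle[:, 0], atol=1e-10)
        np.testing.assert_allclose(ew["t"], oracle[:, 1], atol=1e-10)
        np.testing.assert_allclose(ew["p"], oracle[:, 2], atol=1e-10)
        np.testing.assert_allclose(ew["z"], oracle[:, 3], atol=1e-10)

    def test_perfect_correlation_gives_capped_finite_z(self, beta_matrix, sample_table):
        samples = sample_table(n=6, ages=[1, 2, 4, 6, 8, 10])
        bm = beta_matrix(0.01 * np.array([[1, 2, 4, 6, 8, 10.0]]), samples=samples.sample_ids)
        ew = correlation_screen(bm, samples)
        assert ew["r"].iloc[0] == pytest.approx(1.0)
        assert np.isfinite(ew["z"].iloc[0])
        assert ew["z"].iloc[0] <= Z_MAX
        assert ew["p"].iloc[0] > 0

    def test_constant_probe_undefined_and_excluded(self, beta_matrix, sample_table):
        samples = sample_table(n=5, ages=[1, 2, 3, 4, 5])
        bm = beta_matrix(
            np.array([[0.5] * 5, [0.1, 0.2, 0.3, 0.4, 0.5]]), samples=samples.sample_ids
        )
        ew = correlation_screen(bm, samples)
        assert np.isnan(ew["r"].iloc[0])
        sel = select_top_cpgs(ew, p_threshold=1.0)
        assert "cg0" not in sel["hyper"] + sel["hypo"]

    def test_too_few_samples_rejected(self, beta_matrix, sample_table):
        samples = sample_table(n=3, ages=[1, 2, 3])
        bm = beta_matrix(np.full((2, 3), 0.4), samples=samples.sample_ids)
        with pytest.raises(ValidationError, match=">=4"):
            correlation_screen(bm, samples)


class TestStouffer:
    def test_equal_z_values(self):
        assert stouffer_meta(2.0, 2.0) == pytest.approx(2.8284271247461903, abs=1e-12)

    def test_cancellation(self):
        assert stouffer_meta(1.5, -1.5) == 0.0

    def test_sqrt_n_weights_match_direct_formula(self):
        z = stouffer_meta(2.0, 0.0, weights=(np.sqrt(100), np.sqrt(25)))
        assert z == pytest.approx(20 / np.sqrt(125), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_weights_match_direct_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        z1, z2 = rng.normal(size=2)
        w1, w2 = rng.uniform(0.1, 5.0, size=2)
        expected = (w1 * z1 + w2 * z2) / np.sqrt(w1**2 + w2**2)
        assert stouffer_meta(z1, z2, (w1, w2)) == pytest.approx(expected, abs=1e-12)

    def test_meta_monotone_in_each_z_and_symmetric(self):
        base = stouffer_meta(1.0, 2.0)
        assert stouffer_meta(1.5, 2.0) > base
        assert stouffer_meta(1.0, 2.5) > base
        assert stouffer_meta(2.0, 1.0) == pytest.approx(base, abs=1e-14)

    def test_meta_table_undefined_propagates(self):
        a = pd.DataFrame({"n": 50, "z": [1.0, np.nan], "p": [0.3, np.nan]},
                         index=["cg1", "cg2"])
        b = pd.DataFrame({"n": 40, "z": [2.0, 1.0], "p": [0.04, 0.3]},
                         index=["cg1", "cg2"])
        meta = meta_analysis(a, b)
        assert meta.loc["cg1", "z_meta"] == pytest.approx(3 / np.sqrt(2))
        assert np.isnan(meta.loc["cg2", "z_meta"])
        assert np.isnan(meta.loc["cg2", "p_meta"])


def _ewas_frame(z, p=None, index=None):
    z = np.asarray(z, float)
    p = 2 * stats.norm.sf(np.abs(z)) if p is None else np.asarray(p, float)
    index = index or [f"cg{i:04d}" for i in range(len(z))]
    return pd.DataFrame({"n": 50, "r": np.sign(z) * 0.5, "t": z, "p": p, "z": z},
                        index=pd.Index(index, name="probe_id"))


class TestSelectTopCpgs:
    def test_cap_keeps_largest_abs_z(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(4.0, 9.0, 600)  # all p < 1e-4, positive
        ew = _ewas_frame(z)
        sel = select_top_cpgs(ew, max_per_direction=500)
        assert len(sel["hyper"]) == 500
        kept = set(sel["hyper"])
        dropped_max = ew.loc[~ew.index.isin(kept), "z"].max()
        kept_min = ew.loc[ew.index.isin(kept), "z"].min()
        assert kept_min >= dropped_max

    def test_threshold_filter(self):
        ew = _ewas_frame([5.0, 2.0, 5.5], p=[1e-5, 1e-3, 1e-6], index=["a", "b", "c"])
        sel = select_top_cpgs(ew)
        assert set(sel["hyper"]) == {"a", "c"}
        assert sel["hypo"] == []

    def test_directions_split_by_sign(self):
        ew = _ewas_frame([6.0, -6.0, 5.0, -5.0])
        sel = select_top_cpgs(ew)
        assert sel["hyper"] == ["cg0000", "cg0002"]
        assert sel["hypo"] == ["cg0001", "cg0003"]

    def test_ties_break_deterministically_by_probe_id(self):
        ew = _ewas_frame([6.0] * 5, index=list("edcba"))
        sel1 = select_top_cpgs(ew, max_per_direction=3)
        sel2 = select_top_cpgs(ew.iloc[::-1], max_per_direction=3)
        assert sel1["hyper"] == sel2["hyper"] == ["a", "b", "c"]


class TestDivergence:
    def test_classes(self):
        blood = _ewas_frame([5.0, 5.0, 5.0, 0.5, -5.0], index=list("abcde"))
        oocyte = _ewas_frame([-5.0, 1.0, 5.0, 0.3, -5.0], index=list("abcde"))
        oocyte.loc["b", "p"] = 0.3
        cls = classify_divergent(blood, oocyte)
        assert cls["a"] == "divergent_both"
        assert cls["b"] == "blood_only"
        assert cls["c"] == "concordant_both"
        assert cls["d"] == "neither"
        assert cls["e"] == "concordant_both"

    def test_probe_universe_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            classify_divergent(_ewas_frame([1.0]), _ewas_frame([1.0, 2.0]))

    def test_synthetic_divergent_probes_recovered(self, small_dataset):
        betas, samples, _, truth = small_dataset
        cattle = samples.subset(species="cattle")
        blood = correlation_screen(betas, cattle, tissue="blood")
        oocyte = correlation_screen(betas, cattle, tissue="oocyte")
        cls = classify_divergent(blood, oocyte)
        divergent_truth = truth.index[truth["class"] == "divergent"]
        recovered = (cls[divergent_truth] == "divergent_both").mean()
        assert recovered >= 0.8
        # and no null probe is ever called divergent
        null_probes = truth.index[truth["class"] == "null"]
        assert (cls[null_probes] == "divergent_both").sum() == 0


class TestCrossTissueZ:
    def test_identical_tables_give_r_one(self):
        ew = _ewas_frame(np.linspace(-3, 3, 50))
        assert cross_tissue_z_correlation(ew, ew) == pytest.approx(1.0)

    def test_negated_table_gives_minus_one(self):
        ew = _ewas_frame(np.linspace(-3, 3, 50))
        neg = ew.copy()
        neg["z"] = -neg["z"]
        assert cross_tissue_z_correlation(ew, neg) == pytest.approx(-1.0)

    def test_disjoint_aging_sets_give_near_zero_r(self, small_dataset):
        betas, samples, _, _ = small_dataset
        cattle = samples.subset(species="cattle")
        blood = correlation_screen(betas, cattle, tissue="blood")
        oocyte = correlation_screen(betas, cattle, tissue="oocyte")
        assert abs(cross_tissue_z_correlation(blood, oocyte)) < 0.25


def exact_hypergeom_upper_tail(a, N, K, n):
    """Direct summation oracle: P(X >= a) for X ~ Hypergeom(N, K, n)."""
    total = 0.0
    for k in range(a, min(K, n) + 1):
        total += math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
    return total


class TestEnrichment:
    def test_worked_2x2_example(self):
        # 20 selected of 1000, feature covers 100, a = 10:
        # d = 1000 − 100 − 20 + 10 = 890, OR = (10·890)/(10·90) = 89/9
        background = [f"p{i}" for i in range(1000)]
        feature = set(background[:100])
        selected = background[:10] + background[100:110]
        res = feature_enrichment(selected, background, feature)
        assert (res.a, res.b, res.c, res.d) == (10, 10, 90, 890)
        assert res.odds_ratio == pytest.approx(89 / 9)
        expected_p = exact_hypergeom_upper_tail(10, 1000, 100, 20)
        assert res.p_value == pytest.approx(expected_p, rel=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exact_summation_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(50, 2000))
        K = int(rng.integers(1, N))
        n = int(rng.integers(1, min(N, 200)))
        background = [f"p{i}" for i in range(N)]
        feature = set(rng.choice(background, size=K, replace=False))
        selected = list(rng.choice(background, size=n, replace=False))
        res = feature_enrichment(selected, background, feature)
        assert res.p_value == pytest.approx(
            exact_hypergeom_upper_tail(res.a, N, K, n), rel=1e-9, abs=1e-300
        )

    def test_calibration_under_uniform_selection(self):
        rng = np.random.default_rng(5)
        background = [f"p{i}" for i in range(500)]
        feature = set(background[:100])
        pvals = [
            feature_enrichment(
                rng.choice(background, size=50, replace=False), background, feature
            ).p_value
            for _ in range(200)
        ]
        # discrete p-values are super-uniform; check no inflation of small p
        assert np.mean(np.array(pvals) < 0.05) <= 0.09

    def test_feature_absent_from_selection(self):
        background = [f"p{i}" for i in range(100)]
        res = feature_enrichment(background[50:60], background, set(background[:10]))
        assert res.a == 0
        assert res.odds_ratio == 0.0
        assert res.p_value > 0.6

    def test_infinite_odds_ratio_flagged(self):
        background = [f"p{i}" for i in range(100)]
        feature = set(background[:10])
        res = feature_enrichment(background[:10], background, feature)
        assert res.odds_ratio_infinite
        assert 0 < res.p_value <= 1

    def test_selection_outside_background_rejected(self):
        with pytest.raises(ValidationError, match="subset"):
            feature_enrichment(["x"], ["a", "b"], set())


def _annotation(probes, island_mask):
    return CpGAnnotation(
        pd.DataFrame(
            {
                "probe_id": probes,
                "chromosome": "1",
                "position": np.arange(1, len(probes) + 1) * 100,
                "nearest_gene": "G1",
                "distance_to_tss": 50_000,
                "region_class": "intron",
                "island_status": np.where(island_mask, "island", "non_island"),
            }
        )
    )


class TestIslandComparison:
    def test_known_shift_detected(self):
        rng = np.random.default_rng(9)
        n = 200
        z = np.concatenate([rng.normal(1.0, 1.0, n), rng.normal(0.0, 1.0, n)])
        probes = [f"cg{i}" for i in range(2 * n)]
        ew = _ewas_frame(z, index=probes)
        ann = _annotation(probes, np.arange(2 * n) < n)
        res = island_z_comparison(ew, ann)
        assert res["t"] > 3
        assert res["p"] < 1e-3
        assert res["mean_z_island"] > res["mean_z_non_island"]

    def test_identical_strata_mean_difference_zero(self):
        probes = [f"cg{i}" for i in range(6)]
        ew = _ewas_frame([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=probes)
        ann = _annotation(probes, np.arange(6) < 3)
        res = island_z_comparison(ew, ann)
        assert res["mean_z_island"] == res["mean_z_non_island"]
        assert res["t"] == pytest.approx(0.0, abs=1e-12)

    def test_small_stratum_rejected(self):
        probes = [f"cg{i}" for i in range(4)]
        ew = _ewas_frame([1.0, 2.0, 3.0, 4.0], index=probes)
        ann = _annotation(probes, np.arange(4) < 1)
        with pytest.raises(ValidationError, match="stratum"):
            island_z_comparison(ew, ann)


class TestMeanMethylationByIsland:
    def test_constant_matrix(self, beta_matrix, sample_table):
        samples = sample_table(n=4)
        bm = beta_matrix(np.full((4, 4), 0.5), samples=samples.sample_ids)
        ann = _annotation(bm.probe_ids, np.arange(4) < 2)
        out = mean_methylation_by_island(bm, samples, ann)
        assert (out["mean_beta"] == 0.5).all()

    def test_single_probe_stratum(self, beta_matrix, sample_table):
        samples = sample_table(n=3)
        values = np.array([[0.2, 0.2, 0.2], [0.7, 0.8, 0.9]])
        bm = beta_matrix(values, samples=samples.sample_ids)
        ann = _annotation(bm.probe_ids, np.array([True, False]))
        out = mean_methylation_by_island(bm, samples, ann).set_index("island_status")
        assert out.loc["island", "mean_beta"] == pytest.approx(0.2)
        assert out.loc["non_island", "mean_beta"] == pytest.approx(0.8)

    def test_default_synthetic_oocyte_below_blood_outside_islands(self, small_dataset):
        betas, samples, annotation, _ = small_dataset
        out = mean_methylation_by_island(betas, samples, annotation)
        out = out.set_index(["tissue", "island_status"])
        assert (
            out.loc[("oocyte", "non_island"), "mean_beta"]
            < out.loc[("blood", "non_island"), "mean_beta"]
        )


class TestCpgsNearGene:
    def _toy(self):
        return CpGAnnotation(
            pd.DataFrame(
                {
                    "probe_id": ["cgA", "cgB", "cgC"],
                    "chromosome": ["1", "1", "2"],
                    "position": [200_000, 2_500_000, 1_000_000],
                    "nearest_gene": ["SIRT1", "OTHER", "OTHER2"],
                    # cgA 800 kb upstream of the SIRT1 TSS at 1,000,000
                    "distance_to_tss": [-800_000, 1_500_000, 50_000],
                    "region_class": [
                        "intergenic_upstream",
                        "intergenic_downstream",
                        "intron",
                    ],
                    "island_status": ["non_island"] * 3,
                }
            )
        )

    def test_window_arithmetic(self):
        out = cpgs_near_gene(self._toy(), "SIRT1", flank_bp=1_000_000)
        assert list(out["probe_id"]) == ["cgA"]
        assert out["side"].iloc[0] == "upstream"
        assert out["distance_to_gene_tss"].iloc[0] == -800_000

    def test_zero_flank_keeps_only_tss_probes(self):
        ann = self._toy()
        out = cpgs_near_gene(ann, "SIRT1", flank_bp=0)
        assert len(out) == 0

    def test_result_invariant_to_probe_order(self):
        ann = self._toy()
        shuffled = CpGAnnotation(ann.df.iloc[::-1].reset_index(drop=True))
        a = cpgs_near_gene(ann, "SIRT1", flank_bp=2_000_000)
        b = cpgs_near_gene(shuffled, "SIRT1", flank_bp=2_000_000)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_gene_lists_near_misses(self):
        with pytest.raises(ValidationError, match="SIRT1"):
            cpgs_near_gene(self._toy(), "SIRT")

    def test_gene_coordinate_table_used_when_given(self):
        coords = pd.DataFrame({"gene": ["NEW"], "chromosome": ["2"], "tss": [990_000]})
        out = cpgs_near_gene(self._toy(), "NEW", flank_bp=20_000, gene_coords=coords)
        assert list(out["probe_id"]) == ["cgC"]
        assert out["side"].iloc[0] == "downstream"
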