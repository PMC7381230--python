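import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seroglycan.glycans import partition_library
from seroglycan.stats import (
    correlation_cluster,
    fit_differential,
    fit_variance_prior,
    isotype_correlation,
    normalize_mfi,
    select_hits,
    selected_pair_anova,
    selected_pair_kw_dunn,
    subgroup_median,
    posterior_variance,
    VariancePrior,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Subgroup medians


class TestSubgroupMedian:
    def test_median_of_subgroup_cells(self):
        library = {"g1": "H4N2F2", "g2": "H4N2F3", "g3": "H5N3F4"}
        part = partition_library(library)
        m = make_matrix(
            np.array([[1.0, 2.0, 9.0]]), ["ctrl"], glycans=list(library), library=part
        )
        med = subgroup_median(m)
        f24 = med[(med["subgroup"] == "F2to4") & (med["sample_id"] == "s01")]
        assert f24["median"].iloc[0] == 2.0

    def test_singleton_subgroup(self):
        library = {"g1": "H5N3", "g2": "H4N2F1"}
        part = partition_library(library)
        m = make_matrix(np.array([[3.5, 7.25]]), ["ctrl"], list(library), part)
        med = subgroup_median(m)
        f1 = med[med["subgroup"] == "F1"]
        assert f1["median"].iloc[0] == 7.25
        assert f1["n_glycans"].iloc[0] == 1

    def test_all_subgroup_includes_unknowns(self):
        library = {"g1": "H5N3", "g2": "unknown"}
        part = partition_library(library)
        m = make_matrix(np.array([[2.0, 8.0]]), ["ctrl"], list(library), part)
        med = subgroup_median(m)
        assert med[med["subgroup"] == "all"]["n_glycans"].iloc[0] == 2
        assert med[med["subgroup"] == "undecorated"]["n_glycans"].iloc[0] == 1


# ---------------------------------------------------------------------------
# Selected-pair tests


def groups_fixture(shift_cd=0.0, seed=0, n=(8, 8, 8)):
    rng = np.random.default_rng(seed)
    return {
        "ctrl": rng.normal(0, 1, n[0]),
        "UC": rng.normal(0, 1, n[1]),
        "CD": rng.normal(shift_cd, 1, n[2]),
    }


class TestSelectedPairAnova:
    def test_identical_groups_null(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = selected_pair_anova({"ctrl": vals, "UC": vals, "CD": vals})
        assert {r.comparison for r in res} == {"ctrl_vs_UC", "ctrl_vs_CD"}
        for r in res:
            assert r.statistic == pytest.approx(0.0, abs=1e-12)
            assert r.p_adjusted == pytest.approx(1.0)

    def test_shifted_cd_detected_only_in_cd_pair(self):
        res = selected_pair_anova(groups_fixture(shift_cd=5.0, seed=1))
        by = {r.comparison: r for r in res}
        assert by["ctrl_vs_CD"].p_adjusted < 0.05
        assert by["ctrl_vs_UC"].p_adjusted > 0.05

    def test_bonferroni_identity(self):
        res = selected_pair_anova(groups_fixture(shift_cd=1.0, seed=2))
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, 2 * r.p_raw))
            assert r.p_adjusted >= r.p_raw

    def test_pairwise_matches_pooled_variance_t(self):
        """Cross-check the pairwise statistic against a direct computation
        from scipy's ANOVA machinery (pooled MSW, t with N-k df)."""
        g = groups_fixture(shift_cd=2.0, seed=3, n=(5, 6, 7))
        res = {r.comparison: r for r in selected_pair_anova(g)}
        all_v = np.concatenate([g["ctrl"], g["UC"], g["CD"]])
        dfw = len(all_v) - 3
        msw = sum(np.sum((v - v.mean()) ** 2) for v in g.values()) / dfw
        t_ref = (g["CD"].mean() - g["ctrl"].mean()) / math.sqrt(
            msw * (1 / 5 + 1 / 7)
        )
        assert res["ctrl_vs_CD"].statistic == pytest.approx(t_ref, rel=1e-12)
        p_ref = 2 * sps.t.sf(abs(t_ref), dfw)
        assert res["ctrl_vs_CD"].p_raw == pytest.approx(p_ref, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            selected_pair_anova({"ctrl": [1.0], "UC": [1, 2], "CD": [1, 2]})


class TestSelectedPairKwDunn:
    def test_degenerate_identical_values(self):
        vals = [2.0, 2.0, 2.0]
        res = selected_pair_kw_dunn({"ctrl": vals, "UC": vals, "CD": vals})
        assert all(r.degenerate and r.p_raw == 1.0 for r in res)

    def test_ordered_groups_rank_separation(self):
        res = selected_pair_kw_dunn(
            {"ctrl": [1, 2, 3], "UC": [4, 5, 6], "CD": [7, 8, 9]}
        )
        by = {r.comparison: r for r in res}
        # mean ranks 2, 5, 8 -> CD further from ctrl than UC
        assert by["ctrl_vs_CD"].statistic > by["ctrl_vs_UC"].statistic > 0

    def test_invariance_under_monotone_transform(self):
        g = groups_fixture(shift_cd=1.5, seed=4)
        res_a = selected_pair_kw_dunn(g)
        res_b = selected_pair_kw_dunn({k: np.exp(v) for k, v in g.items()})
        for a, b in zip(res_a, res_b):
            assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
            assert a.p_raw == pytest.approx(b.p_raw, rel=1e-12)

    def test_dunn_z_hand_computed(self):
        # groups {1,2,3},{4,5,6}: pooled ranks 1..6, no ties
        res = selected_pair_kw_dunn(
            {"ctrl": [1, 2, 3], "UC": [4, 5, 6], "CD": [7, 8, 9]}
        )
        by = {r.comparison: r for r in res}
        n = 9
        se = math.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        assert by["ctrl_vs_UC"].statistic == pytest.approx((5 - 2) / se)
        assert by["ctrl_vs_CD"].statistic == pytest.approx((8 - 2) / se)


# ---------------------------------------------------------------------------
# Differential reactivity


def random_matrix(seed, n_a=3, n_b=3, n_glycans=20, delta=0.0, heterosked=True):
    rng = np.random.default_rng(seed)
    sds = rng.uniform(0.3, 2.0, n_glycans) if heterosked else np.ones(n_glycans)
    base = rng.normal(8, 1, n_glycans)
    a = base + rng.normal(0, 1, (n_a, n_glycans)) * sds
    b = base + delta + rng.normal(0, 1, (n_b, n_glycans)) * sds
    values = np.abs(np.vstack([a, b]))
    return make_matrix(values, ["ctrl"] * n_a + ["CD"] * n_b)


def oracle_moderated(matrix, group_a, group_b, prior):
    """Independent closed-form evaluation of the posterior-variance
    moderated t, computed per glycan with plain Python loops."""
    rows_a = [s for s in matrix.samples if matrix.sample_groups[s] == group_a]
    rows_b = [s for s in matrix.samples if matrix.sample_groups[s] == group_b]
    na, nb = len(rows_a), len(rows_b)
    d = na + nb - 2
    out = {}
    for g in matrix.glycans:
        xa = [matrix.values.loc[s, g] for s in rows_a]
        xb = [matrix.values.loc[s, g] for s in rows_b]
        ma, mb = sum(xa) / na, sum(xb) / nb
        ss = sum((x - ma) ** 2 for x in xa) + sum((x - mb) ** 2 for x in xb)
        s2 = ss / d
        if math.isinf(prior.df):
            post = prior.scale
            df_total = math.inf
        else:
            post = (prior.df * prior.scale + d * s2) / (prior.df + d)
            df_total = prior.df + d
        t = (mb - ma) / math.sqrt(post * (1 / na + 1 / nb))
        if math.isinf(df_total):
            p = 2 * sps.norm.sf(abs(t))
        else:
            p = 2 * sps.t.sf(abs(t), df_total)
        out[g] = (mb - ma, post, t, p)
    return out


class TestFitDifferential:
    def test_equal_group_means_null(self):
        values = np.tile(np.array([[5.0, 6.0, 7.0]]), (6, 1))
        # within-group spread, identical group means
        values += np.array([-1.0, 1.0, 0.0, -1.0, 1.0, 0.0])[:, None]
        m = make_matrix(values, ["ctrl"] * 3 + ["CD"] * 3)
        res = fit_differential(m, "ctrl", "CD")
        assert res["logfc"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_moderation_off_equals_student_t(self):
        m = random_matrix(seed=10)
        res = fit_differential(m, "ctrl", "CD", use_moderation=False)
        a = m.values.iloc[:3].to_numpy()
        b = m.values.iloc[3:].to_numpy()
        t_ref, p_ref = sps.ttest_ind(b, a, axis=0, equal_var=True)
        np.testing.assert_allclose(res["t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p_raw"].to_numpy(), p_ref, atol=1e-10)

    def test_zero_prior_df_limit_is_ordinary_t(self):
        """With d0 = 0 the posterior variance is the per-glycan variance and
        the moderated t collapses to the ordinary pooled t."""
        s2 = np.array([0.5, 1.0, 2.0])
        post = posterior_variance(s2, df=4, prior=VariancePrior(df=0.0, scale=1.0))
        np.testing.assert_allclose(post, s2, atol=1e-12)

    def test_moderated_matches_closed_form_oracle(self):
        for seed in range(5):
            m = random_matrix(seed=seed)
            res = fit_differential(m, "ctrl", "CD", use_moderation=True)
            oracle = oracle_moderated(m, "ctrl", "CD", res.attrs["prior"])
            for g, (logfc, post, t, p) in oracle.items():
                row = res.loc[g]
                assert row["logfc"] == pytest.approx(logfc, abs=1e-8)
                assert row["posterior_s2"] == pytest.approx(post, abs=1e-8)
                assert row["t"] == pytest.approx(t, abs=1e-8)
                assert row["p_raw"] == pytest.approx(p, abs=1e-8)

    def test_posterior_variance_bracketing(self):
        m = random_matrix(seed=11)
        res = fit_differential(m, "ctrl", "CD", use_moderation=True)
        prior = res.attrs["prior"]
        lo = np.minimum(res["s2"], prior.scale)
        hi = np.maximum(res["s2"], prior.scale)
        assert ((res["posterior_s2"] >= lo - 1e-12) & (res["posterior_s2"] <= hi + 1e-12)).all()

    def test_logfc_antisymmetry(self):
        m = random_matrix(seed=12, delta=1.0)
        ab = fit_differential(m, "ctrl", "CD")
        ba = fit_differential(m, "CD", "ctrl")
        np.testing.assert_allclose(ab["logfc"].to_numpy(), -ba["logfc"].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(ab["p_raw"].to_numpy(), ba["p_raw"].to_numpy(), atol=1e-12)

    def test_all_zero_variance_falls_back_to_ordinary_t(self, caplog):
        values = np.tile(np.array([[5.0, 6.0]]), (4, 1))
        m = make_matrix(values, ["ctrl"] * 2 + ["CD"] * 2)
        import logging

        with caplog.at_level(logging.WARNING):
            res = fit_differential(m, "ctrl", "CD", use_moderation=True)
        assert "falling back" in caplog.text
        assert res.attrs["prior"] is None

    def test_prior_fit_recovers_hyperparameters(self):
        """Method-of-moments on variances drawn from a scaled inverse
        chi-square-like prior recovers (d0, s0^2) approximately."""
        rng = np.random.default_rng(5)
        d, d0, s0 = 10, 8.0, 1.5
        true_var = s0 * d0 / rng.chisquare(d0, 5000)
        s2 = true_var * rng.chisquare(d, 5000) / d
        prior = fit_variance_prior(s2, df=d)
        assert prior.df == pytest.approx(d0, rel=0.15)
        assert prior.scale == pytest.approx(s0, rel=0.1)


class TestSelectHits:
    @staticmethod
    def frame(rows):
        return pd.DataFrame(
            rows,
            columns=["logfc", "p_raw", "p_adjusted", "t"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_hit_rule_and_direction(self):
        res = self.frame(
            [
                [4.02, 0.004, 0.02, 5.0],  # increased hit
                [1.9, 0.001, 0.01, 4.0],  # fails fold threshold
                [-2.5, 0.03, 0.1, -3.0],  # decreased hit
                [2.5, 0.06, 0.2, 2.0],  # fails alpha
            ]
        )
        hits = select_hits(res)
        assert [(h.glycan_id, h.direction) for h in hits] == [
            ("g0", "increased"),
            ("g2", "decreased"),
        ]

    def test_threshold_is_strict_and_alpha_inclusive(self):
        res = self.frame([[2.0, 0.05, 0.05, 2.0], [2.0001, 0.05, 0.05, 2.0]])
        hits = select_hits(res)
        assert [h.glycan_id for h in hits] == ["g1"]

    def test_sorted_by_absolute_logfc(self):
        res = self.frame([[2.1, 0.01, 0.01, 2.0], [-3.5, 0.01, 0.01, -3.0], [2.8, 0.01, 0.01, 2.5]])
        hits = select_hits(res)
        assert [h.glycan_id for h in hits] == ["g1", "g2", "g0"]


# ---------------------------------------------------------------------------
# Isotype correlation


class TestIsotypeCorrelation:
    def test_identical_vectors_r_one(self):
        rng = np.random.default_rng(6)
        v = np.abs(rng.normal(8, 2, (2, 30)))
        igg = make_matrix(v, ["ctrl", "CD"])
        igm = make_matrix(v.copy(), ["ctrl", "CD"])
        res = isotype_correlation(igg, igm)
        np.testing.assert_allclose(res["r"], 1.0, atol=1e-12)

    def test_negated_vector_r_minus_one(self):
        rng = np.random.default_rng(7)
        v = np.abs(rng.normal(8, 2, (1, 30)))
        igg = make_matrix(v, ["ctrl"])
        igm = make_matrix(20.0 - v, ["ctrl"])
        res = isotype_correlation(igg, igm)
        assert res["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        igg = make_matrix(np.full((1, 10), 5.0), ["ctrl"])
        igm = make_matrix(np.abs(np.random.default_rng(0).normal(8, 1, (1, 10))), ["ctrl"])
        res = isotype_correlation(igg, igm)
        assert res["degenerate"].iloc[0]
        assert np.isnan(res["r"].iloc[0])


# ---------------------------------------------------------------------------
# Clustering


def brute_force_complete_linkage(dist: np.ndarray):
    """Oracle: re-scan every cross-pair leaf distance at every step."""
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}  # active id -> leaves
    ids = {i: i for i in range(n)}  # active id -> scipy id
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                d = max(dist[x, y] for x in clusters[a] for y in clusters[b])
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        merges.append((ids[a], ids[b], d))
        clusters[a] = clusters[a] | clusters[b]
        ids[a] = next_id
        del clusters[b], ids[b]
        next_id += 1
    return merges


class TestCorrelationCluster:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(8)
        base = np.abs(rng.normal(8, 2, 20))
        v = np.vstack([base, base + rng.normal(0, 3, 20), base])
        m = make_matrix(v, ["ctrl"] * 3)
        res = correlation_cluster(m)
        first = res.merges[0]
        assert {first[0], first[1]} == {0, 2}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(9)
        m = make_matrix(np.abs(rng.normal(8, 2, (5, 15))), ["ctrl"] * 5)
        res = correlation_cluster(m)
        r = res.correlation.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0, atol=1e-12)

    def test_merge_sequence_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(20):
            n = int(rng.integers(3, 9))
            v = np.abs(rng.normal(8, 2, (n, 12)))
            m = make_matrix(v, ["ctrl"] * n)
            res = correlation_cluster(m)
            dist = 1.0 - np.corrcoef(v)
            np.fill_diagonal(dist, 0.0)
            expected = brute_force_complete_linkage(dist)
            assert len(res.merges) == len(expected)
            for got, want in zip(res.merges, expected):
                assert got[0] == want[0] and got[1] == want[1]
                assert got[2] == pytest.approx(want[2], abs=1e-10)

    def test_constant_sample_is_fatal(self):
        v = np.vstack([np.full(10, 5.0), np.arange(10.0)])
        m = make_matrix(v, ["ctrl"] * 2)
        with pytest.raises(ValueError, match="s01"):
            correlation_cluster(m)

    def test_leaf_order_covers_all_samples(self):
        rng = np.random.default_rng(11)
        m = make_matrix(np.abs(rng.normal(8, 2, (6, 10))), ["ctrl"] * 6)
        res = correlation_cluster(m)
        assert sorted(res.sample_order) == sorted(m.samples)


# ---------------------------------------------------------------------------
# MFI normalization


class TestNormalizeMfi:
    def test_ratio(self):
        assert normalize_mfi(1000.0, 10.0) == 100.0

    def test_scale_invariance(self):
        assert normalize_mfi(2000.0, 20.0) == normalize_mfi(1000.0, 10.0)

    def test_non_positive_concentration_error(self):
        with pytest.raises(ValueError):
            normalize_mfi(1000.0, 0.0)
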