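import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from elevmicro.core_io import CommunityTable, DistanceMatrix, metadata_from_records
from elevmicro.gradient_stats import (
    _gower_center,
    _hat,
    anosim,
    bh_fdr,
    classify_elevation_response,
    elevation_factor_matrices,
    fit_trend,
    partial_mantel,
    permanova,
    spearman_test,
    wilcoxon_rank_sum,
    within_group_dissimilarity_trend,
)
from tests.conftest import random_distance_matrix


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_p(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, p_values):
        from statsmodels.stats.multitest import multipletests

        q = bh_fdr(p_values)
        expected = multipletests(p_values, method="fdr_bh")[1]
        assert np.allclose(q, expected)
        order = np.argsort(p_values, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSpearman:
    def test_exact_small_n_against_enumeration_distribution(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
        rho, p = spearman_test(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)
        # enumeration: all 720 rank orders, fraction with |rho| >= observed
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        for perm in itertools.permutations(ry):
            if abs(np.corrcoef(rx, perm)[0, 1]) >= abs(obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 720)

    def test_large_n_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(scale=2.0, size=40)
        rho, p = spearman_test(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestClassify:
    @staticmethod
    def _design_table(abundances: dict[str, list[int]]) -> tuple[CommunityTable, pd.DataFrame]:
        elevations = [501.0, 2298.0, 2690.0, 3110.0, 3150.0, 3271.0, 3431.0]
        rows, counts = [], []
        i = 0
        for elev in elevations:
            for rep in range(3):
                sid = f"s{i}"
                rows.append({"sample_id": sid, "subject_id": f"u{i}",
                             "elevation_m": elev, "body_site": "palm"})
                counts.append([abundances[t][len(counts) % 7] if False else 0
                               for t in abundances])
                i += 1
        # abundance per taxon indexed by site
        arr = np.zeros((len(rows), len(abundances)), dtype=int)
        for j, t in enumerate(abundances):
            site_vals = abundances[t]
            for k, row in enumerate(rows):
                site = elevations.index(row["elevation_m"])
                arr[k, j] = site_vals[site]
        table = CommunityTable(pd.DataFrame(
            arr, index=[r["sample_id"] for r in rows], columns=list(abundances)))
        return table, metadata_from_records(rows)

    def test_monotone_taxon_is_tolerant(self):
        table, meta = self._design_table({
            "up": [10, 20, 30, 40, 50, 60, 70],
            "flat": [100] * 7,
            "down": [70, 60, 50, 40, 30, 20, 10],
        })
        result = {c.taxon_id: c for c in
                  classify_elevation_response(table, meta, mean_abund_floor=0.0)}
        assert result["up"].taxon_class == "tolerant" and result["up"].spearman_rho > 0
        assert result["down"].taxon_class == "sensitive" and result["down"].spearman_rho < 0

    def test_constant_taxon_not_significant(self):
        table, meta = self._design_table({
            "up": [10, 20, 30, 40, 50, 60, 70],
            "const": [50] * 7,
        })
        # 'const' has constant counts but varying relative abundance; build a
        # truly constant relative-abundance case instead: equal proportions
        table2 = CommunityTable(table.counts.assign(const=100, up=100))
        result = {c.taxon_id: c for c in
                  classify_elevation_response(table2, meta, mean_abund_floor=0.0)}
        assert result["const"].taxon_class == "not_significant"

    def test_too_few_samples_rejected(self, small_table, toy_metadata):
        with pytest.raises(ValueError):
            classify_elevation_response(
                small_table, toy_metadata.iloc[:3], mean_abund_floor=0.0
            )


class TestTrend:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = fit_trend(2 * x + 1, x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_null_pvalues_uniform(self):
        """Monte-Carlo calibration: independent noise gives uniform p."""
        rng = np.random.default_rng(1)
        x = np.arange(20.0)
        ps = [fit_trend(rng.normal(size=20), x).p_value for _ in range(150)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestWithinGroupTrend:
    def test_identical_compositions_zero_slope(self):
        vals = np.zeros((6, 6))
        dm = DistanceMatrix([f"s{i}" for i in range(6)], vals, "bray_curtis")
        meta = metadata_from_records(
            [{"sample_id": f"s{i}", "subject_id": f"u{i}",
              "elevation_m": 500.0 if i < 3 else 3000.0, "body_site": "palm"}
             for i in range(6)]
        )
        fit = within_group_dissimilarity_trend(dm, meta)
        assert fit.slope == pytest.approx(0.0)

    def test_matches_hand_ols_on_two_sites(self):
        ids = [f"s{i}" for i in range(6)]
        vals = np.zeros((6, 6))
        within_a = {(0, 1): 0.1, (0, 2): 0.2, (1, 2): 0.3}
        within_b = {(3, 4): 0.5, (3, 5): 0.6, (4, 5): 0.7}
        for (i, j), v in {**within_a, **within_b}.items():
            vals[i, j] = vals[j, i] = v
        vals[:3, 3:] = 0.9
        vals[3:, :3] = 0.9
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix(ids, vals, "bray_curtis")
        meta = metadata_from_records(
            [{"sample_id": f"s{i}", "subject_id": f"u{i}",
              "elevation_m": 1000.0 if i < 3 else 3000.0, "body_site": "palm"}
             for i in range(6)]
        )
        fit = within_group_dissimilarity_trend(dm, meta)
        y = [0.1, 0.2, 0.3, 0.5, 0.6, 0.7]
        x = [1000.0] * 3 + [3000.0] * 3
        ref = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope)
        assert fit.r_squared == pytest.approx(ref.rvalue**2)

    def test_singleton_sites_skipped(self):
        elevations = [500, 500, 2000, 2000, 3000, 3000, 4000]
        dm = random_distance_matrix(7, seed=2, ids=[f"s{i}" for i in range(7)])
        meta = metadata_from_records(
            [{"sample_id": f"s{i}", "subject_id": f"u{i}",
              "elevation_m": elevations[i], "body_site": "palm"}
             for i in range(7)]
        )
        fit = within_group_dissimilarity_trend(dm, meta)
        assert fit.n == 3  # one pair per two-sample site; the singleton skipped


def _permanova_f_oracle(d: np.ndarray, labels: np.ndarray) -> float:
    """Single-factor pseudo-F via explicit Gower projection (brute force)."""
    n = len(labels)
    g = _gower_center(d)
    x0 = np.ones((n, 1))
    dummies = pd.get_dummies(pd.Series(labels.astype(str)), drop_first=True).to_numpy(float)
    x1 = np.hstack([x0, dummies])
    h1, h0 = _hat(x1), _hat(x0)
    df1 = int(round(np.trace(h1))) - 1
    ss = np.trace((h1 - h0) @ g)
    ssr = np.trace((np.eye(n) - h1) @ g)
    return (ss / df1) / (ssr / (n - 1 - df1))


class TestPermanova:
    def test_block_design_r_squared(self):
        """All variation between groups: R^2 = 1 (within-distances are 0)."""
        d = np.ones((6, 6))
        d[:3, :3] = 0
        d[3:, 3:] = 0
        np.fill_diagonal(d, 0)
        ids = [f"s{i}" for i in range(6)]
        dm = DistanceMatrix(ids, d, "toy")
        meta = pd.DataFrame({"sample_id": ids, "grp": ["a"] * 3 + ["b"] * 3}
                            ).set_index("sample_id", drop=False)
        res = permanova(dm, meta, ["grp"], permutations=999, seed=0)
        assert res[0].r_squared == pytest.approx(1.0)
        assert res[0].p_value <= 0.12  # 36 partition-preserving relabelings / 720

    def test_matches_vegan_adonis2_two_terms(self):
        """Frozen oracle: SS/R^2/F computed by vegan::adonis2 (by='terms')."""
        rng = np.random.default_rng(42)
        n = 12
        grp = ["a"] * 6 + ["b"] * 6
        cov = rng.normal(0, 1, n).round(3)
        pts = np.vstack([rng.normal(0, 1, (6, 3)), rng.normal(1, 1, (6, 3))]
                        ) + 0.5 * cov[:, None]
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts)).round(6)
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(ids, d, "euclid")
        meta = pd.DataFrame({"sample_id": ids, "grp": grp, "cov": cov}
                            ).set_index("sample_id", drop=False)
        res = permanova(dm, meta, ["grp", "cov"], permutations=99, seed=1)
        assert res[0].sum_of_squares == pytest.approx(15.817, abs=1e-3)
        assert res[0].r_squared == pytest.approx(0.38870, abs=1e-5)
        assert res[0].pseudo_f == pytest.approx(8.9886, abs=1e-4)
        assert res[1].sum_of_squares == pytest.approx(9.038, abs=1e-3)
        assert res[1].r_squared == pytest.approx(0.22211, abs=1e-5)
        assert res[1].pseudo_f == pytest.approx(5.1364, abs=1e-4)
        assert res[2].term == "Residual"
        assert res[2].r_squared == pytest.approx(0.38919, abs=1e-5)

    def test_single_factor_matches_exhaustive_oracle(self):
        """999-permutation p within sampling error of the exhaustive p (n=6)."""
        dm = random_distance_matrix(6, seed=9)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        meta = pd.DataFrame({"sample_id": dm.ids, "grp": labels}
                            ).set_index("sample_id", drop=False)
        res = permanova(dm, meta, ["grp"], permutations=999, seed=3)
        f_obs = _permanova_f_oracle(dm.values, labels)
        assert res[0].pseudo_f == pytest.approx(f_obs)
        count = sum(
            _permanova_f_oracle(dm.values, labels[list(p)]) >= f_obs - 1e-12
            for p in itertools.permutations(range(6))
        )
        p_exact = count / 720
        se = math.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res[0].p_value - p_exact) < 4 * se + 2e-3

    def test_single_level_term_rejected(self):
        dm = random_distance_matrix(4, seed=0)
        meta = pd.DataFrame({"sample_id": dm.ids, "grp": ["a"] * 4}
                            ).set_index("sample_id", drop=False)
        with pytest.raises(ValueError):
            permanova(dm, meta, ["grp"], permutations=9, seed=0)

    def test_r_squared_partition_sums_to_one(self):
        dm = random_distance_matrix(10, seed=4)
        rng = np.random.default_rng(5)
        meta = pd.DataFrame(
            {"sample_id": dm.ids,
             "grp": rng.choice(["a", "b"], 10),
             "cov": rng.normal(size=10)}
        ).set_index("sample_id", drop=False)
        res = permanova(dm, meta, ["grp", "cov"], permutations=9, seed=0)
        assert sum(r.r_squared for r in res) == pytest.approx(1.0)


class TestAnosim:
    def test_perfect_separation_r_one(self):
        d = np.ones((6, 6)) * 0.9
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "toy")
        r, p = anosim(dm, ["a"] * 3 + ["b"] * 3, permutations=999, seed=0)
        assert r == pytest.approx(1.0)

    def test_hand_computed_four_samples(self):
        # distances: within pairs (a1,a2)=1, (b1,b2)=2; between = 3,4,5,6
        d = np.array(
            [[0, 1, 3, 4], [1, 0, 5, 6], [3, 5, 0, 2], [4, 6, 2, 0]], float
        )
        dm = DistanceMatrix(["a1", "a2", "b1", "b2"], d, "toy")
        r, _ = anosim(dm, ["a", "a", "b", "b"], permutations=99, seed=0)
        # ranks: 1->1, 2->2, 3->3, 4->4, 5->5, 6->6; rw = (1+2)/2, rb = 4.5
        expected = (4.5 - 1.5) / (4 * 3 / 4)
        assert r == pytest.approx(expected)

    def test_matches_skbio(self):
        import skbio

        dm = random_distance_matrix(10, seed=6)
        labels = ["a"] * 5 + ["b"] * 5
        r, _ = anosim(dm, labels, permutations=99, seed=1)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.values, dm.ids), np.array(labels), permutations=99
        )
        assert r == pytest.approx(ref["test statistic"])

    def test_random_labels_center_r_at_zero(self):
        rng = np.random.default_rng(7)
        dm = random_distance_matrix(8, seed=8)
        rs = []
        for _ in range(60):
            labels = rng.permutation(["a"] * 4 + ["b"] * 4)
            r, _ = anosim(dm, labels, permutations=1, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.1

    def test_one_group_rejected(self):
        dm = random_distance_matrix(4, seed=0)
        with pytest.raises(ValueError):
            anosim(dm, ["a"] * 4, permutations=9, seed=0)


class TestPartialMantel:
    def test_identical_matrices_r_one(self):
        dm = random_distance_matrix(7, seed=10)
        control = random_distance_matrix(7, seed=11, ids=dm.ids)
        r, _ = partial_mantel(dm, dm, control, permutations=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_partial_r_matches_manual_residual_formula(self):
        a = random_distance_matrix(8, seed=12)
        b = random_distance_matrix(8, seed=13, ids=a.ids)
        c = random_distance_matrix(8, seed=14, ids=a.ids)
        r, _ = partial_mantel(a, b, c, permutations=9, seed=0)
        iu = np.triu_indices(8, 1)
        va, vb, vc = a.values[iu], b.values[iu], c.values[iu]
        rab = np.corrcoef(va, vb)[0, 1]
        rac = np.corrcoef(va, vc)[0, 1]
        rbc = np.corrcoef(vb, vc)[0, 1]
        expected = (rab - rac * rbc) / math.sqrt((1 - rac**2) * (1 - rbc**2))
        assert r == pytest.approx(expected)

    def test_plain_mantel_matches_skbio(self):
        import skbio

        a = random_distance_matrix(9, seed=15)
        b = random_distance_matrix(9, seed=16, ids=a.ids)
        r, _ = partial_mantel(a, b, None, permutations=99, seed=0)
        ref_r, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(a.values, a.ids),
            skbio.DistanceMatrix(b.values, b.ids),
            permutations=0,
        )
        assert r == pytest.approx(ref_r)

    def test_p_matches_exhaustive_enumeration_n5(self):
        a = random_distance_matrix(5, seed=17)
        b = random_distance_matrix(5, seed=18, ids=a.ids)
        r_obs, p = partial_mantel(a, b, None, permutations=999, seed=2)
        iu = np.triu_indices(5, 1)
        vb = b.values[iu]
        count, total = 0, 0
        for perm in itertools.permutations(range(5)):
            va = a.values[np.ix_(perm, perm)][iu]
            if np.corrcoef(va, vb)[0, 1] >= r_obs - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
        se = math.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p - p_exact) < 4 * se + 5e-3

    def test_mismatched_ids_rejected(self):
        a = random_distance_matrix(5, seed=19)
        b = random_distance_matrix(5, seed=20, ids=[f"y{i}" for i in range(5)])
        with pytest.raises(ValueError):
            partial_mantel(a, b, None, permutations=9, seed=0)


class TestWilcoxon:
    def test_extreme_separation_exact_p(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert w == 6.0  # smallest possible rank sum for n=3
        assert p == pytest.approx(2 / 20)  # both tails of C(6,3)=20 orderings

    def test_identical_multisets_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        _, p = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_normal_approximation_with_ties(self):
        x = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 6, 6]
        y = [3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 8]
        _, p = wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_strong_shift_small_p(self):
        rng = np.random.default_rng(22)
        x = rng.normal(0, 1, 40)
        y = rng.normal(3, 1, 40)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestElevationFactorMatrices:
    def test_same_subject_same_covariates_zero_gower(self):
        meta = metadata_from_records(
            [
                {"sample_id": "s1", "subject_id": "u1", "elevation_m": 501.0,
                 "body_site": "palm", "gender": "f", "age": 30, "height": 170,
                 "weight": 60},
                {"sample_id": "s2", "subject_id": "u1", "elevation_m": 3431.0,
                 "body_site": "palm", "gender": "f", "age": 30, "height": 170,
                 "weight": 60},
            ]
        )
        d_elev, d_host = elevation_factor_matrices(meta)
        assert d_host.values[0, 1] == pytest.approx(0.0)
        assert d_elev.values[0, 1] == pytest.approx(2930.0)

    def test_all_categorical_gower_is_mismatch_fraction(self):
        meta = metadata_from_records(
            [
                {"sample_id": "s1", "subject_id": "u1", "elevation_m": 100.0,
                 "body_site": "palm", "gender": "f", "age": 1, "height": 1,
                 "weight": 1},
                {"sample_id": "s2", "subject_id": "u2", "elevation_m": 100.0,
                 "body_site": "forehead", "gender": "m", "age": 1, "height": 1,
                 "weight": 1},
            ]
        )
        _, d_host = elevation_factor_matrices(meta)
        # numeric covariates are constant (distance 0); 3/3 categorical differ
        assert d_host.values[0, 1] == pytest.approx(3 / 6)

    def test_missing_field_rejected(self, toy_metadata):
        meta = toy_metadata.drop(columns=["weight"])
        with pytest.raises(ValueError, match="weight"):
            elevation_factor_matrices(meta)
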