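import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from fmtnet import (
    AsvTable,
    bray_curtis,
    kruskal_wallis,
    pairwise_wilcoxon,
    pcoa,
    permanova,
    richness,
    shannon,
    tmm_factors,
)


class TestAlpha:
    @pytest.mark.parametrize("counts,expected", [
        ((0, 0, 5, 1), 2),
        ((0, 0, 0), 0),
    ])
    def test_richness_examples(self, counts, expected):
        assert richness(counts) == expected

    def test_richness_matches_direct_scan(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, size=200)
        assert richness(x) == sum(1 for v in x if v > 0)

    @pytest.mark.parametrize("counts,expected", [
        ((10, 10), 1.0),
        ((7, 0, 0), 0.0),
        ((2, 1, 1), 1.5),
    ])
    def test_shannon_examples(self, counts, expected):
        assert shannon(counts, base=2) == pytest.approx(expected)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.integers(0, 30, size=15)
            if x.sum() == 0:
                continue
            h = shannon(x, base=2)
            assert 0.0 <= h <= np.log2(max(richness(x), 1)) + 1e-12

    def test_shannon_zero_total_errors(self):
        with pytest.raises(ValueError):
            shannon((0, 0))


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = AsvTable(pd.DataFrame({"u": [3, 5], "v": [3, 5]}, index=["a", "b"]))
        assert bray_curtis(t)["u", "v"] == 0.0

    def test_disjoint_supports_one(self):
        t = AsvTable(pd.DataFrame({"u": [3, 0], "v": [0, 5]}, index=["a", "b"]))
        assert bray_curtis(t)["u", "v"] == pytest.approx(1.0)

    def test_hand_example(self):
        t = AsvTable(pd.DataFrame({"u": [6, 2], "v": [2, 2]}, index=["a", "b"]))
        assert bray_curtis(t)["u", "v"] == pytest.approx(1.0 / 3.0)

    def test_symmetry_identity_bounds(self, random_table):
        t = AsvTable(random_table.counts + 1)  # avoid zero-total edge
        d = np.asarray(bray_curtis(t).data)
        assert np.allclose(d, d.T, atol=1e-12)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()


class TestPcoa:
    def test_line_geometry_recovered(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abc"))
        res = pcoa(dm)
        axis1 = res.samples.iloc[:, 0].to_numpy()
        gaps = np.abs(np.diff(axis1))
        assert gaps == pytest.approx([1.0, 2.0], abs=1e-8)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(8)])
        res = pcoa(dm)
        coords = res.samples.to_numpy()
        recon = squareform(pdist(coords))
        assert np.allclose(recon, dm.data, atol=1e-8)

    def test_positive_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 2))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(7)])
        res = pcoa(dm)
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        pos = res.eigvals[res.eigvals > 0].sum()
        assert pos == pytest.approx(np.trace(b), rel=1e-8)

    def test_duplicate_samples_identical_coordinates(self):
        pts = np.array([[0.0], [0.0], [2.0], [5.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("wxyz"))
        res = pcoa(dm)
        assert np.allclose(res.samples.iloc[0], res.samples.iloc[1], atol=1e-9)

    def test_too_few_samples(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            pcoa(dm)


def _two_group_line_dm():
    pts = np.array([[0.0], [1.0], [10.0], [11.0]])
    return DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))


class TestPermanova:
    def test_worked_example_exhaustive(self):
        res = permanova(_two_group_line_dm(), ["g1", "g1", "g2", "g2"],
                        n_perm="exhaustive")
        assert res.statistic == pytest.approx(200.0, rel=1e-9)
        assert res.pvalue == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_all_identical_points_degenerate(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            permanova(_two_group_line_dm(), ["g1", "g2", "g2", "g2"])

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(dm, groups, n_perm=9, seed=0)
        ref = skbio_permanova(dm, grouping=groups, permutations=9)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-10)


class TestRankTests:
    def test_kruskal_all_equal_convention(self):
        res = kruskal_wallis([5, 5, 5, 5], ["a", "a", "b", "b"])
        assert (res.statistic, res.pvalue) == (0.0, 1.0)

    def test_rank_sum_matches_exact_enumeration(self):
        # perfectly separated groups of 3: enumerate all rank assignments
        values = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        labels = ["a"] * 3 + ["b"] * 3
        observed = pairwise_wilcoxon(values, labels)[("a", "b")]
        ranks = scipy.stats.rankdata(values)

        def u_stat(idx_a):
            ra = ranks[list(idx_a)].sum()
            return ra - 3 * 4 / 2  # U = R_a - n_a(n_a+1)/2

        u_obs = u_stat([0, 1, 2])
        u_all = [u_stat(c) for c in itertools.combinations(range(6), 3)]
        mid = 3 * 3 / 2
        p_exact = np.mean([abs(u - mid) >= abs(u_obs - mid) for u in u_all])
        assert observed == pytest.approx(p_exact, abs=1e-12)

    def test_kruskal_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        alpha, reps = 0.05, 1000
        rejections = 0
        for _ in range(reps):
            x = rng.normal(size=18)
            g = np.repeat(["a", "b", "c"], 6)
            rejections += kruskal_wallis(x, g).pvalue < alpha
        half_width = 1.96 * np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rejections / reps - alpha) <= half_width


class TestTmm:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]},
                          index=["x", "y", "z"])
        assert np.allclose(tmm_factors(df).to_numpy(), 1.0)

    def test_depth_doubling_gives_unit_factor(self):
        rng = np.random.default_rng(0)
        col = rng.integers(10, 100, size=50)
        df = pd.DataFrame({"a": col, "b": 2 * col},
                          index=[f"g{i}" for i in range(50)])
        assert np.allclose(tmm_factors(df).to_numpy(), 1.0, atol=1e-12)

    def test_spike_fixture_frozen_oracle(self):
        # 100 equal-count taxa plus one taxon 10x in sample B; expected
        # factors computed independently with edgeR::calcNormFactors
        c = np.full((101, 2), 100)
        c[0, 1] = 1000
        df = pd.DataFrame(c, index=[f"g{i}" for i in range(101)],
                          columns=["A", "B"])
        f = tmm_factors(df)
        assert f["A"] == pytest.approx(1.04360, abs=1e-4)
        assert f["B"] == pytest.approx(0.95822, abs=1e-4)

    def test_geometric_mean_is_one(self, random_table):
        f = tmm_factors(AsvTable(random_table.counts + 1))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger_reference(self, tmp_path):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.integers(0, 500, size=(200, 5)) + 1,
                          index=[f"g{i}" for i in range(200)],
                          columns=list("abcde"))
        df.to_csv(tmp_path / "counts.tsv", sep="\t")
        script = (
            "suppressMessages(library(edgeR));"
            f"x <- read.delim('{tmp_path / 'counts.tsv'}', row.names=1);"
            "d <- calcNormFactors(DGEList(counts=as.matrix(x)));"
            "cat(d$samples$norm.factors, sep='\\n')"
        )
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(tmm_factors(df).to_numpy(), ref, atol=1e-5)

    def test_disjoint_sample_gets_unit_factor(self, caplog):
        df = pd.DataFrame({"ref": [10, 10, 0, 10], "other": [0, 0, 7, 0]},
                          index=list("wxyz"))
        with caplog.at_level("WARNING"):
            f = tmm_factors(df, ref_sample="ref")
        assert f["other"] == pytest.approx(1.0)
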