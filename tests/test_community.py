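"""Bray-Curtis, clustering, PCoA, envfit, PERMANOVA and the read threshold."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rasbiofilter.community import (
    CommunityTable,
    DistanceMatrix,
    bray_curtis,
    complete_linkage,
    dendrogram_to_newick,
    envfit,
    med_minimum_abundance,
    pcoa,
    permanova,
    relative_abundance,
    within_group_similarity,
)


def table_from(rows, ids=None, groups=None):
    data = pd.DataFrame(
        rows, index=ids or [f"s{i}" for i in range(len(rows))]
    )
    g = pd.Series(groups, index=data.index) if groups is not None else None
    return CommunityTable(data, g)


def random_distance_matrix(rng, n):
    """Random metric-ish symmetric matrix with distinct off-diagonals."""
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(n)], d)


class TestRelativeAbundance:
    def test_simple_rows(self):
        t = relative_abundance(table_from([[2.0, 2.0], [3.0, 1.0]]))
        np.testing.assert_allclose(t.data.to_numpy(), [[0.5, 0.5], [0.75, 0.25]])

    def test_normalized_rows_unchanged(self):
        rows = [[0.75, 0.25, 0.0]]
        t = relative_abundance(table_from(rows))
        np.testing.assert_allclose(t.data.to_numpy(), rows)

    def test_empty_row_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            relative_abundance(table_from([[0.0, 0.0], [1.0, 1.0]]))

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            table_from([[1.0, -0.1]])


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        d = bray_curtis(table_from([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        assert d.values[0, 1] == pytest.approx(0.0)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_raw_count_formula(self):
        d = bray_curtis(table_from([[2.0, 1.0], [1.0, 3.0]]), normalize=False)
        assert d.values[0, 1] == pytest.approx(3 / 7)

    def test_matches_scipy_reference(self, rng):
        from scipy.spatial.distance import pdist, squareform

        counts = rng.integers(0, 50, size=(8, 12)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1.0
        t = table_from(counts.tolist())
        ours = bray_curtis(t, normalize=False).values
        ref = squareform(pdist(counts, metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_invariant_to_taxon_order(self, rng):
        counts = rng.integers(1, 30, size=(5, 7)).astype(float)
        data = pd.DataFrame(counts, index=list("abcde"))
        shuffled = data[rng.permutation(data.columns)]
        d1 = bray_curtis(CommunityTable(data)).values
        d2 = bray_curtis(CommunityTable(shuffled)).values
        np.testing.assert_allclose(d1, d2, atol=1e-14)

    @given(
        hnp.arrays(
            float,
            (4, 6),
            elements=st.floats(0.0, 100.0, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetric_bounded(self, counts):
        counts[:, 0] += 1.0  # no empty samples
        d = bray_curtis(table_from(counts.tolist())).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()

    def test_all_zero_pair_warns_distance_zero(self):
        t = table_from([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            d = bray_curtis(t, normalize=False)
        assert d.values[0, 1] == 0.0


class TestCompleteLinkage:
    def test_forced_merge_order(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]]),
        )
        merges = complete_linkage(d)
        assert merges[0] == (0, 1, pytest.approx(0.1))
        assert merges[1][2] == pytest.approx(0.9)

    def test_equal_distances_final_height(self):
        n = 4
        vals = np.full((n, n), 0.6)
        np.fill_diagonal(vals, 0.0)
        merges = complete_linkage(DistanceMatrix(list("abcd"), vals))
        assert merges[-1][2] == pytest.approx(0.6)
        # deterministic tie-break: first merge joins the smallest indices
        assert merges[0][:2] == (0, 1)

    def test_heights_nondecreasing(self, rng):
        merges = complete_linkage(random_distance_matrix(rng, 7))
        heights = [h for _, _, h in merges]
        assert all(h2 >= h1 for h1, h2 in zip(heights, heights[1:]))

    def test_matches_scipy_reference(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        for _ in range(5):
            d = random_distance_matrix(rng, 6)
            ours = complete_linkage(d)
            ref = linkage(squareform(d.values), method="complete")
            np.testing.assert_allclose(
                [m[2] for m in ours], ref[:, 2], atol=1e-10
            )
            # identical cluster memberships at every merge
            def leafsets(merges, n):
                members = {i: frozenset([i]) for i in range(n)}
                out = []
                for k, (a, b, _) in enumerate(merges):
                    members[n + k] = members[a] | members[b]
                    out.append(members[n + k])
                return out

            ours_sets = leafsets(ours, 6)
            ref_sets = leafsets([(int(a), int(b), h) for a, b, h, _ in ref], 6)
            assert ours_sets == ref_sets

    def test_newick_roundtrip_leaves(self, rng):
        import io

        import skbio

        d = random_distance_matrix(rng, 6)
        nwk = dendrogram_to_newick(complete_linkage(d), d.ids)
        tree = skbio.TreeNode.read(io.StringIO(nwk))
        assert sorted(t.name for t in tree.tips()) == sorted(d.ids)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            complete_linkage(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestPcoa:
    def test_euclidean_roundtrip(self, rng):
        d = random_distance_matrix(rng, 8)
        ord_ = pcoa(d)
        coords = ord_.coordinates
        recon = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(recon, d.values, atol=1e-8)

    def test_duplicate_sample_coincides(self, rng):
        pts = rng.normal(size=(5, 2))
        pts = np.vstack([pts, pts[0]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ord_ = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        np.testing.assert_allclose(
            ord_.coordinates[0], ord_.coordinates[5], atol=1e-8
        )

    def test_two_clusters_separate_on_axis1(self):
        vals = np.zeros((6, 6))
        vals[:3, 3:] = 1.0
        vals[3:, :3] = 1.0
        ord_ = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], vals))
        ax1 = ord_.coordinates[:, 0]
        assert np.ptp(np.sign(ax1[:3])) == 0 and np.ptp(np.sign(ax1[3:])) == 0
        assert np.sign(ax1[0]) != np.sign(ax1[3])

    def test_matches_skbio_reference(self, rng):
        import skbio

        d = random_distance_matrix(rng, 7)
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.ids))
        n_pos = ours.percent_variance.size
        np.testing.assert_allclose(
            ours.eigenvalues[:n_pos],
            ref.eigvals.to_numpy()[:n_pos],
            atol=1e-8,
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, :2]),
            np.abs(ref.samples.to_numpy()[:, :2]),
            atol=1e-6,
        )

    def test_percent_variance_sums_to_100(self, rng):
        ord_ = pcoa(random_distance_matrix(rng, 6))
        assert ord_.percent_variance.sum() == pytest.approx(100.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestEnvfit:
    def test_env_equal_to_axis1(self, rng):
        ord_ = pcoa(random_distance_matrix(rng, 8))
        res = envfit(ord_, ord_.coordinates[:, 0], n_perm=199, seed=0)
        assert abs(res.dim1) == pytest.approx(1.0, abs=1e-9)
        assert res.dim2 == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(1 / 200)

    def test_constant_env_degenerate(self, rng):
        ord_ = pcoa(random_distance_matrix(rng, 6))
        res = envfit(ord_, np.ones(6), n_perm=199, seed=0)
        assert res.r_squared == 0.0 and res.p == 1.0 and res.degenerate
        assert res.dim1 == res.dim2 == 0.0

    def test_unit_direction_vector(self, rng):
        ord_ = pcoa(random_distance_matrix(rng, 9))
        res = envfit(ord_, rng.normal(size=9), n_perm=99, seed=0)
        assert res.dim1**2 + res.dim2**2 == pytest.approx(1.0)

    def test_p_uniform_under_null(self, rng):
        from scipy import stats

        ord_ = pcoa(random_distance_matrix(rng, 12))
        pvals = [
            envfit(ord_, rng.normal(size=12), n_perm=199, seed=rng).p
            for _ in range(150)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert min(pvals) >= 1 / 200

    def test_length_mismatch_rejected(self, rng):
        ord_ = pcoa(random_distance_matrix(rng, 6))
        with pytest.raises(ValueError):
            envfit(ord_, np.ones(5))


def naive_permanova_stats(d, labels):
    """Direct double-loop sums-of-squares implementation."""
    n = len(labels)
    ss_total = sum(
        d[i, j] ** 2 for i, j in itertools.combinations(range(n), 2)
    ) / n
    ss_within = 0.0
    uniq = sorted(set(labels))
    for g in uniq:
        idx = [i for i, l in enumerate(labels) if l == g]
        if len(idx) > 1:
            ss_within += sum(
                d[i, j] ** 2 for i, j in itertools.combinations(idx, 2)
            ) / len(idx)
    k = len(uniq)
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        vals = np.zeros((6, 6))
        vals[:3, 3:] = 0.8
        vals[3:, :3] = 0.8
        d = DistanceMatrix([f"s{i}" for i in range(6)], vals)
        res = permanova(d, ["x"] * 3 + ["y"] * 3, n_perm=999, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p >= 1 / 1000

    def test_matches_naive_oracle(self, rng):
        d = random_distance_matrix(rng, 8)
        labels = ["a", "a", "a", "b", "b", "b", "b", "a"]
        res = permanova(d, labels, n_perm=99, seed=0)
        f_ref, r2_ref = naive_permanova_stats(d.values, labels)
        assert res.F == pytest.approx(f_ref, abs=1e-10)
        assert res.r_squared == pytest.approx(r2_ref, abs=1e-10)

    def test_matches_skbio_statistic(self, rng):
        import skbio

        d = random_distance_matrix(rng, 9)
        labels = ["a"] * 4 + ["b"] * 5
        res = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values, d.ids), grouping=labels, permutations=0
        )
        assert res.F == pytest.approx(float(ref["test statistic"]), abs=1e-10)

    def test_r2_complement_identity(self, rng):
        """R^2 + SS_within/SS_total = 1 by construction."""
        d = random_distance_matrix(rng, 10)
        labels = list("aabbbccdda")
        res = permanova(d, labels, n_perm=99, seed=0)
        _, r2 = naive_permanova_stats(d.values, labels)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)

    def test_p_uniform_under_null(self, rng):
        from scipy import stats

        pvals = []
        for _ in range(100):
            d = random_distance_matrix(rng, 10)
            labels = rng.permutation(["a"] * 5 + ["b"] * 5)
            pvals.append(permanova(d, labels, n_perm=199, seed=int(rng.integers(2**31))).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert min(pvals) >= 1 / 200

    def test_label_errors(self, rng):
        d = random_distance_matrix(rng, 4)
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "a", "a"], n_perm=99)
        with pytest.raises(ValueError):
            permanova(d, pd.Series({"s0": "a", "s1": "b"}), n_perm=99)


class TestWithinGroupSimilarity:
    def test_identical_samples_full_similarity(self):
        vals = np.zeros((3, 3))
        d = DistanceMatrix(["a", "b", "c"], vals)
        out = within_group_similarity(d, ["g", "g", "g"])
        assert out.loc["g", "mean_similarity"] == pytest.approx(100.0)
        assert out.loc["g", "sd_similarity"] == pytest.approx(0.0)

    def test_single_pair(self):
        vals = np.array([[0.0, 0.348], [0.348, 0.0]])
        d = DistanceMatrix(["a", "b"], vals)
        out = within_group_similarity(d, ["g", "g"])
        assert out.loc["g", "mean_similarity"] == pytest.approx(65.2)

    def test_matches_bruteforce_over_pairs(self, rng):
        d = random_distance_matrix(rng, 5)
        clipped = DistanceMatrix(d.ids, np.clip(d.values, 0, 1))
        out = within_group_similarity(clipped, ["g"] * 5)
        sims = [
            100 * (1 - clipped.values[i, j])
            for i, j in itertools.combinations(range(5), 2)
        ]
        assert out.loc["g", "mean_similarity"] == pytest.approx(np.mean(sims))
        assert out.loc["g", "sd_similarity"] == pytest.approx(np.std(sims, ddof=1))
        assert out.loc["g", "n_pairs"] == 10

    def test_singleton_group_excluded_with_warning(self):
        vals = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.6], [0.4, 0.6, 0.0]])
        d = DistanceMatrix(["a", "b", "c"], vals)
        with pytest.warns(UserWarning, match="<2 samples"):
            out = within_group_similarity(d, ["g", "g", "h"])
        assert list(out.index) == ["g"]


class TestMedMinimumAbundance:
    @pytest.mark.parametrize(
        "reads, expected",
        [
            (50_000, 1),
            (18_850_000, 377),  # bacterial V6-scale dataset
            (6_150_000, 123),  # archaeal V6-scale dataset
            (1_050_000, 21),  # bacterial V4-V5-scale dataset
            (49_999, 1),
            (1, 1),
        ],
    )
    def test_threshold_rule(self, reads, expected):
        assert med_minimum_abundance(reads) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            med_minimum_abundance(0)
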