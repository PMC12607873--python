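import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from hma_fidelity.beta import (
    DistMatrix,
    bray_curtis,
    compare_groups,
    dispersion_distances,
    extract_group_dissimilarities,
    pcoa,
    permanova,
    permdisp,
)
from hma_fidelity.tables import PairingMap, renormalize
from tests.conftest import human, make_table, mouse


def bray_curtis_oracle(x):
    """Naive double-loop evaluation of sum|xi-xj| / sum(xi+xj)."""
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for t in range(x.shape[0]):
                num += abs(x[t, i] - x[t, j])
                den += x[t, i] + x[t, j]
            d[i, j] = num / den
    return d


def permanova_f_oracle(d, labels):
    """Pseudo-F from first principles on a small design."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    a = len(groups)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += sum(
            d[idx[i], idx[j]] ** 2
            for i in range(len(idx)) for j in range(i + 1, len(idx))
        ) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_exact_p(d, labels):
    """Full enumeration over distinct two-group label assignments."""
    labels = np.asarray(labels)
    n = len(labels)
    g0 = sorted(set(labels.tolist()))[0]
    k = int(np.sum(labels == g0))
    f_obs = permanova_f_oracle(d, labels)
    count = total = 0
    for combo in itertools.combinations(range(n), k):
        perm = np.array(["B"] * n, dtype=object)
        perm[list(combo)] = "A"
        total += 1
        if permanova_f_oracle(d, perm) >= f_obs - 1e-12:
            count += 1
    return count / total


class TestBrayCurtis:
    def test_hand_case(self):
        table = make_table([[60, 20], [40, 30], [0, 50]])
        d = bray_curtis(table)
        assert d.d[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_identical_and_disjoint(self):
        table = make_table([[50, 50, 0], [50, 50, 0], [0, 0, 100]])
        d = bray_curtis(table).d
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.random((rng.integers(2, 21), rng.integers(2, 13))) * 10 + 0.01
            table = make_table(x)
            np.testing.assert_allclose(
                bray_curtis(table).d, bray_curtis_oracle(x), atol=1e-12
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.random((10, 5)) + 0.1
        d1 = bray_curtis(make_table(x)).d
        d2 = bray_curtis(make_table(x * 37.5)).d
        np.testing.assert_allclose(d1, d2, atol=1e-12)

    def test_matches_scipy_braycurtis(self):
        rng = np.random.default_rng(3)
        x = rng.random((12, 6)) + 0.01
        ours = bray_curtis(make_table(x)).d
        ref = squareform(pdist(x.T, metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(make_table([[100, 0], [0, 0]]))


class TestPcoa:
    def test_three_points_on_a_line(self):
        # points at 0, 3, 4 -> distances d01=3, d02=4, d12=1
        d = DistMatrix(["a", "b", "c"], [[0, 3, 4], [3, 0, 1], [4, 1, 0]])
        ord_ = pcoa(d)
        coords = ord_.coordinates[:, 0]
        recon = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(recon, d.d, atol=1e-9)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(8, 3))
        d = DistMatrix([f"p{i}" for i in range(8)], squareform(pdist(pts)))
        ord_ = pcoa(d)
        recon = squareform(pdist(ord_.coordinates))
        np.testing.assert_allclose(recon, d.d, atol=1e-9)
        positive = ord_.eigenvalues > 1e-12
        assert ord_.proportion_explained[positive].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_matrix_gives_zero_coordinates(self):
        d = DistMatrix(["a", "b", "c"], np.zeros((3, 3)))
        np.testing.assert_allclose(pcoa(d).coordinates, 0.0)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistMatrix(["a", "b"], [[0, 0.5], [0.4, 0]])

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        x = rng.random((15, 7)) + 0.01
        table = renormalize(make_table(x))
        d = bray_curtis(table)
        ours = pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.d, ids=d.ids), method="eigh"
        )
        n_pos = int((ours.eigenvalues > 1e-6).sum())
        np.testing.assert_allclose(
            ours.eigenvalues[:n_pos], ref.eigvals.values[:n_pos], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates[:, :2]),
            np.abs(ref.samples.values[:, :2]),
            atol=1e-6,
        )


class TestPermanova:
    def _toy(self):
        d = np.full((4, 4), 0.9)
        d[0, 1] = d[1, 0] = d[2, 3] = d[3, 2] = 0.1
        np.fill_diagonal(d, 0.0)
        return DistMatrix(list("wxyz"), d), ["A", "A", "B", "B"]

    def test_toy_exact_enumeration(self):
        dist, labels = self._toy()
        assert permanova_exact_p(dist.d, labels) == pytest.approx(2 / 6)

    def test_sampler_converges_to_enumeration(self):
        dist, labels = self._toy()
        res = permanova(dist, labels, n_perm=10_000, seed=0)
        se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
        assert abs(res.p_value - 1 / 3) < 3 * se + 1e-4

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.random((8, 6)) + 0.05
        dist = bray_curtis(make_table(x))
        labels = ["A", "A", "A", "B", "B", "B"]
        r1 = permanova(dist, labels, n_perm=99, seed=4)
        swapped = ["B" if l == "A" else "A" for l in labels]
        r2 = permanova(dist, swapped, n_perm=99, seed=4)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_equidistant_points_are_null(self):
        # four equidistant points: SS_between/(a-1) equals SS_within/(n-a),
        # so F = 1 for every labeling and the permutation p is exactly 1
        d = np.full((4, 4), 0.7)
        np.fill_diagonal(d, 0.0)
        dist = DistMatrix(list("abcd"), d)
        res = permanova(dist, ["A", "A", "B", "B"], n_perm=999, seed=1)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_f_matches_oracle_on_random_designs(self):
        rng = np.random.default_rng(21)
        for sizes in [(2, 2), (3, 2), (3, 3), (4, 3)]:
            n = sum(sizes)
            x = rng.random((10, n)) + 0.05
            dist = bray_curtis(make_table(x))
            labels = ["A"] * sizes[0] + ["B"] * sizes[1]
            res = permanova(dist, labels, n_perm=9, seed=0)
            assert res.statistic == pytest.approx(
                permanova_f_oracle(dist.d, labels), abs=1e-12
            )

    def test_matches_skbio_statistic(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(17)
        x = rng.random((12, 9)) + 0.02
        dist = bray_curtis(renormalize(make_table(x)))
        labels = ["A"] * 4 + ["B"] * 5
        ours = permanova(dist, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dist.d, ids=dist.ids),
            grouping=labels, permutations=99,
        )
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_single_group_rejected(self):
        d = DistMatrix(["a", "b"], [[0, 0.5], [0.5, 0]])
        with pytest.raises(ValueError, match="two groups"):
            permanova(d, ["A", "A"], seed=0)

    def test_seed_is_mandatory(self):
        dist, labels = self._toy()
        with pytest.raises(ValueError, match="seed"):
            permanova(dist, labels)


class TestPermdisp:
    def test_equal_dispersion_low_f(self):
        # two congruent triangles far apart: identical within-group geometry
        pts = np.array([[0, 0], [1, 0], [0, 1], [50, 50], [51, 50], [50, 51]], float)
        d = DistMatrix([f"p{i}" for i in range(6)], squareform(pdist(pts)))
        res = permdisp(d, ["A"] * 3 + ["B"] * 3, n_perm=999, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.5

    def test_contrasting_dispersion_detected(self):
        pts = np.array([[0, 0], [0.001, 0], [0, 0.001],
                        [10, 0], [-10, 5], [3, -9]], float)
        d = DistMatrix([f"p{i}" for i in range(6)], squareform(pdist(pts)))
        res = permdisp(d, ["A"] * 3 + ["B"] * 3, n_perm=999, seed=0)
        assert res.statistic > 20
        # observed labeling and its complement share the extreme F, so the
        # enumeration floor over C(6,3)=20 partitions is ~2/20
        assert res.p_value < 0.15

    def test_distances_non_negative_and_match_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(23)
        x = rng.random((14, 10)) + 0.02
        dist = bray_curtis(renormalize(make_table(x)))
        labels = ["A"] * 5 + ["B"] * 5
        ours = dispersion_distances(dist, labels)
        assert (ours >= 0).all()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = skbio.stats.distance.permdisp(
                skbio.DistanceMatrix(dist.d, ids=dist.ids),
                grouping=labels, permutations=9, seed=0, test="centroid",
                dimensions=10,
            )
        res = permdisp(dist, labels, n_perm=99, seed=0)
        # skbio truncates negative axes instead of applying the imaginary
        # correction, so agreement is approximate on semi-metric input
        assert res.statistic == pytest.approx(ref["test statistic"], rel=0.02)

    def test_singleton_group_rejected(self):
        d = DistMatrix(["a", "b", "c"], squareform([1.0, 2.0, 1.5]))
        with pytest.raises(ValueError, match="fewer than 2"):
            permdisp(d, ["A", "B", "B"], n_perm=9, seed=0)


class TestExtractGroupDissimilarities:
    def test_three_donor_partition_counts(self):
        ids = ["h1", "h2", "h3", "g1", "g2", "g3"]
        rng = np.random.default_rng(2)
        d = squareform(rng.random(15))
        dist = DistMatrix(ids, d)
        meta = [human(f"h{i}", f"d{i}") for i in (1, 2, 3)]
        meta += [mouse(f"m{i}", f"d{i}", f"g{i}") for i in (1, 2, 3)]
        pairing = PairingMap(
            [(f"h{i}", f"g{i}") for i in (1, 2, 3)],
            {f"g{i}": {f"m{i}"} for i in (1, 2, 3)},
        )
        grouped = extract_group_dissimilarities(dist, meta, pairing)
        counts = {k: len(v) for k, v in grouped.categories.items()}
        assert counts == {
            "donor_donor": 3, "mouse_mouse": 3,
            "donor_paired_recipient": 3, "donor_other_recipient": 6,
        }
        total = sum(counts.values())
        assert total == 15  # every off-diagonal pair in exactly one category

    def test_unknown_id_rejected(self):
        dist = DistMatrix(["h1", "??"], [[0, 0.5], [0.5, 0]])
        meta = [human("h1", "d1"), mouse("m1", "d1", "g1")]
        pairing = PairingMap([("h1", "g1")], {"g1": {"m1"}})
        with pytest.raises(ValueError, match=r"\?\?"):
            extract_group_dissimilarities(dist, meta, pairing)


class TestCompareGroups:
    def test_kruskal_hand_value(self):
        res = compare_groups(
            {"a": [1, 2, 3], "b": [10, 11, 12], "c": [20, 21, 22]},
            method="kruskal_dunn",
        )
        assert res.statistic == pytest.approx(7.2, abs=1e-12)
        assert set(res.pairwise) == {("a", "b"), ("a", "c"), ("b", "c")}
        assert all(0 < p <= 1 for p in res.pairwise.values())

    def test_identical_groups_null(self):
        res = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.p_value >= 0.99

    def test_anova_equal_means(self):
        res = compare_groups(
            {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [2.0, 1.0]},
            method="anova_tukey",
        )
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            res = compare_groups({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_dunn_bonferroni_detects_extreme_pair(self):
        rng = np.random.default_rng(0)
        groups = {
            "low": list(rng.normal(0, 1, 30)),
            "mid": list(rng.normal(1, 1, 30)),
            "high": list(rng.normal(10, 1, 30)),
        }
        res = compare_groups(groups, method="kruskal_dunn")
        assert res.pairwise[("high", "low")] < 0.001
        assert res.pairwise[("high", "low")] < res.pairwise[("low", "mid")]
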