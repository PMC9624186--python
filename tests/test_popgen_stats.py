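import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage

from hierstruct import (
    DistanceMatrix,
    GenotypeMatrix,
    SimulationSpec,
    amova_three_level,
    fst_distribution_summary,
    nei_distance,
    nei_distance_matrix,
    nm_from_fst,
    pairwise_fst,
    pairwise_fst_matrix,
    parametric_gst,
    pcoa,
    simulate_genotypes,
    star_tree,
    upgma,
    wc_theta,
)
from hierstruct.genotype_data import allele_frequencies
from hierstruct.popgen_stats import genotype_mismatch_matrix

from conftest import random_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def anova_theta(g, pops):
    """Weir-Cockerham theta via indicator-variable random-effects ANOVA.

    Independent route: per allele, treat presence as a 0/1 response of gene
    copies nested in individuals nested in populations, compute the three
    mean squares and convert them to variance components.
    """
    num = den = 0.0
    for l in range(g.n_loci):
        pop_genos = []
        alleles = set()
        for pop in pops:
            rows = g.pop_indices(pop)
            geno = g.alleles[rows, l, :]
            geno = geno[(geno != g.missing_code).all(axis=1)]
            pop_genos.append(geno)
            alleles.update(int(a) for a in geno.ravel())
        if len(alleles) < 2 or any(len(x) == 0 for x in pop_genos):
            continue
        n = np.array([len(x) for x in pop_genos], dtype=float)
        r = len(pops)
        nbar = n.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
        for allele in sorted(alleles):
            # y[pop][ind][copy] = indicator of this allele
            ss_p = ss_i = ss_g = 0.0
            ybar = sum((geno == allele).sum() for geno in pop_genos) / (2 * n.sum())
            for geno in pop_genos:
                y = (geno == allele).astype(float)
                ybar_pop = y.mean()
                ss_p += 2 * len(geno) * (ybar_pop - ybar) ** 2
                ybar_ind = y.mean(axis=1)
                ss_i += 2 * ((ybar_ind - ybar_pop) ** 2).sum()
                ss_g += ((y - ybar_ind[:, None]) ** 2).sum()
            ms_p = ss_p / (r - 1)
            ms_i = ss_i / (n.sum() - r)
            ms_g = ss_g / n.sum()
            a = (ms_p - ms_i) / (2 * nc)
            b = (ms_i - ms_g) / 2.0
            c = ms_g
            num += a
            den += a + b + c
    return num / den


def brute_force_amova_ss(d2, pop_of, grp_of):
    """Sums of squares by explicit pair enumeration."""
    n = len(pop_of)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_wp = 0.0
    for p in set(pop_of):
        idx = [i for i in range(n) if pop_of[i] == p]
        ss_wp += sum(
            d2[i, j] for ii, i in enumerate(idx) for j in idx[ii + 1:]
        ) / len(idx)
    ss_wg = 0.0
    for gr in set(grp_of):
        idx = [i for i in range(n) if grp_of[i] == gr]
        ss_wg += sum(
            d2[i, j] for ii, i in enumerate(idx) for j in idx[ii + 1:]
        ) / len(idx)
    return ss_total - ss_wg, ss_wg - ss_wp, ss_wp


def brute_force_upgma(labels, values):
    """Plain agglomeration via scipy average linkage (independent code path)."""
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(values), method="average")
    heights = {}
    members = {i: [lab] for i, lab in enumerate(labels)}
    for step, (a, b, h, _) in enumerate(Z):
        new = len(labels) + step
        members[new] = sorted(members[int(a)] + members[int(b)])
        heights[frozenset(members[new])] = h / 2.0
    return heights


def collect_clades(node, out=None):
    if out is None:
        out = {}
    if not node.is_leaf:
        out[frozenset(node.leaf_labels())] = node.height
        for c in node.children:
            collect_clades(c, out)
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


class TestDistanceMatrix:
    def test_symmetry_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_diagonal_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.1, 1.0], [1.0, 0.0]]))

    def test_tsv_roundtrip(self, tmp_path):
        m = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float))
        p = tmp_path / "d.tsv"
        m.to_tsv(str(p))
        m2 = DistanceMatrix.from_tsv(str(p))
        assert m2.labels == m.labels
        assert np.allclose(m2.values, m.values)


class TestPairwiseFst:
    def _fixed_demes(self, n=10):
        alleles = np.concatenate(
            [np.full((n, 5, 2), 1), np.full((n, 5, 2), 2)]
        )
        return GenotypeMatrix(
            [f"i{j}" for j in range(2 * n)],
            ["A"] * n + ["B"] * n,
            alleles,
            [f"L{j}" for j in range(5)],
        )

    def test_fixed_alternate_alleles(self):
        g = self._fixed_demes()
        assert pairwise_fst(g, "A", "B") == pytest.approx(1.0)
        assert pairwise_fst(g, "A", "B", estimator="gst") == pytest.approx(1.0)

    def test_null_close_to_zero(self):
        spec = SimulationSpec(tree=star_tree(2, 0.001, sizes=200), n_loci=50,
                              alleles_per_locus=6)
        g, _ = simulate_genotypes(spec, seed=0)
        theta = pairwise_fst(g, "D1", "D2")
        assert abs(theta) < 0.05

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(1)
        for seed in range(5):
            g = random_matrix(rng, n_ind=16, n_loci=2, n_pops=2, max_allele=4)
            expect = anova_theta(g, ["Pop1", "Pop2"])
            assert pairwise_fst(g, "Pop1", "Pop2") == pytest.approx(expect, abs=1e-10)

    def test_monomorphic_rejected(self):
        g = GenotypeMatrix(
            ["a", "b"], ["A", "B"],
            np.full((2, 1, 2), 3), ["L1"],
        )
        with pytest.raises(ValueError, match="polymorphic"):
            pairwise_fst(g, "A", "B")

    def test_matrix_builder(self):
        rng = np.random.default_rng(2)
        g = random_matrix(rng, n_ind=30, n_loci=5, n_pops=3, max_allele=6)
        m = pairwise_fst_matrix(g)
        assert m.labels == ["Pop1", "Pop2", "Pop3"]
        assert (m.values >= 0).all()


class TestThetaRecovery:
    @pytest.mark.parametrize("f_drift", [0.105, 0.33, 0.53])
    def test_recovers_parametric_gst(self, f_drift):
        spec = SimulationSpec(tree=star_tree(16, f_drift, sizes=50), n_loci=50,
                              alleles_per_locus=8)
        g, freqs = simulate_genotypes(spec, seed=17)
        target = parametric_gst(freqs)
        theta = wc_theta(g)
        assert abs(theta - target) < 0.05


class TestNmFromFst:
    def test_formula(self):
        assert nm_from_fst(0.25) == pytest.approx(0.75)
        assert nm_from_fst(0.5) == pytest.approx(0.25)

    def test_boundary(self):
        assert nm_from_fst(1.0) == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            nm_from_fst(0.0)
        with pytest.raises(ValueError):
            nm_from_fst(-0.1)


class TestNeiDistance:
    def _table(self, pa, pb, n=50):
        rng = np.random.default_rng(0)
        ga = rng.choice(len(pa), size=(n, 1, 2), p=pa)
        gb = rng.choice(len(pb), size=(n, 1, 2), p=pb)
        g = GenotypeMatrix(
            [f"i{j}" for j in range(2 * n)],
            ["A"] * n + ["B"] * n,
            np.concatenate([ga, gb]),
            ["L1"],
        )
        return allele_frequencies(g)

    def test_identical_zero(self):
        t = self._table([0.5, 0.5], [0.5, 0.5])
        t.freqs[("B", 0)] = dict(t.freqs[("A", 0)])
        assert nei_distance(t, "A", "B") == pytest.approx(0.0)

    def test_hand_computation(self):
        # p_a=(.5,.5), p_b=(1,0): I = 0.5/sqrt(0.5) -> D = 0.3466
        t = self._table([0.5, 0.5], [1.0, 0.0])
        t.freqs[("A", 0)] = {0: 0.5, 1: 0.5}
        t.freqs[("B", 0)] = {0: 1.0}
        d = nei_distance(t, "A", "B")
        assert d == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-12)
        assert d == pytest.approx(0.3466, abs=1e-4)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pa = rng.dirichlet([1] * 4)
            pb = rng.dirichlet([1] * 4)
            t = self._table(pa, pb)
            assert nei_distance(t, "A", "B") == pytest.approx(
                nei_distance(t, "B", "A"))

    def test_disjoint_alleles_infinite(self):
        t = self._table([1.0, 0.0], [1.0, 0.0])
        t.freqs[("A", 0)] = {0: 1.0}
        t.freqs[("B", 0)] = {1: 1.0}
        assert nei_distance(t, "A", "B") == math.inf

    def test_unbiased_corrects_sample_size(self):
        rng = np.random.default_rng(4)
        spec = SimulationSpec(tree=star_tree(2, 0.2, sizes=30), n_loci=20,
                              alleles_per_locus=6)
        g, _ = simulate_genotypes(spec, seed=5)
        std = nei_distance(g, "D1", "D2", variant="standard")
        unb = nei_distance(g, "D1", "D2", variant="unbiased")
        # unbiased removes the upward finite-sample bias
        assert unb < std

    def test_matrix_builder(self):
        rng = np.random.default_rng(5)
        g = random_matrix(rng, n_ind=30, n_loci=5, n_pops=3, max_allele=6)
        m = nei_distance_matrix(g)
        assert np.allclose(m.values, m.values.T)


class TestAMOVA:
    def _toy(self):
        # 3 groups x 2 pops x 5 individuals
        rng = np.random.default_rng(6)
        spec = SimulationSpec(tree=star_tree(6, 0.3, sizes=5), n_loci=8,
                              alleles_per_locus=4)
        g, _ = simulate_genotypes(spec, seed=7)
        grouping = {"D1": "G1", "D2": "G1", "D3": "G2", "D4": "G2",
                    "D5": "G3", "D6": "G3"}
        return g, grouping

    def test_percentages_sum_to_100(self):
        g, grouping = self._toy()
        res = amova_three_level(g, grouping, n_permutations=25, seed=0)
        assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)

    def test_matches_brute_force_ss(self):
        g, grouping = self._toy()
        res = amova_three_level(g, grouping, n_permutations=0)
        d2 = genotype_mismatch_matrix(g)
        pop_of = [g.populations.index(p) for p in g.pop_labels]
        grp_of = [grouping[p] for p in g.pop_labels]
        ss_ag, ss_ap, ss_wp = brute_force_amova_ss(d2, pop_of, grp_of)
        assert res.ss["among_groups"] == pytest.approx(ss_ag)
        assert res.ss["among_pops_within_groups"] == pytest.approx(ss_ap)
        assert res.ss["within_pops"] == pytest.approx(ss_wp)

    def test_panmixia_small_between_components(self):
        spec = SimulationSpec(tree=star_tree(8, 0.001, sizes=25), n_loci=20,
                              alleles_per_locus=6)
        g, _ = simulate_genotypes(spec, seed=8)
        grouping = {f"D{i+1}": ("G1" if i < 4 else "G2") for i in range(8)}
        res = amova_three_level(g, grouping, n_permutations=0)
        assert res.percentages["among_groups"] < 5.0
        assert res.percentages["among_pops_within_groups"] < 5.0

    def test_within_pct_decreases_with_drift(self):
        pcts = []
        for f_drift in (0.05, 0.2, 0.5):
            spec = SimulationSpec(tree=star_tree(6, f_drift, sizes=10), n_loci=10,
                                  alleles_per_locus=6)
            g, _ = simulate_genotypes(spec, seed=9)
            grouping = {f"D{i+1}": ("G1" if i < 3 else "G2") for i in range(6)}
            res = amova_three_level(g, grouping, n_permutations=0)
            pcts.append(res.percentages["within_pops"])
        assert pcts[0] > pcts[1] > pcts[2]

    def test_permutation_pvalues_in_range(self):
        g, grouping = self._toy()
        res = amova_three_level(g, grouping, n_permutations=49, seed=1)
        for v in res.p_values.values():
            assert 0.0 < v <= 1.0

    def test_structured_data_significant(self):
        g, grouping = self._toy()
        res = amova_three_level(g, grouping, n_permutations=99, seed=2)
        assert res.p_values["phi_ST"] <= 0.05

    def test_single_group_rejected(self):
        g, _ = self._toy()
        with pytest.raises(ValueError, match="2 groups"):
            amova_three_level(g, {p: "G" for p in g.populations})

    def test_mismatch_distance_values(self):
        g = GenotypeMatrix(
            ["a", "b", "c"], ["p", "p", "p"],
            np.array([[[1, 2]], [[1, 1]], [[2, 1]]]), ["L1"],
        )
        d = genotype_mismatch_matrix(g)
        assert d[0, 1] == 1.0  # {1,2} vs {1,1}
        assert d[0, 2] == 0.0  # {1,2} vs {2,1}: unordered equal
        assert d[1, 2] == 1.0


class TestUPGMA:
    def test_three_taxon_hand_example(self):
        m = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float))
        tree = upgma(m)
        assert tree.newick() == "((A:1,B:1):1,C:2);"

    def test_two_taxa(self):
        m = DistanceMatrix(["A", "B"], np.array([[0, 3], [3, 0]], dtype=float))
        tree = upgma(m)
        assert tree.height == pytest.approx(1.5)

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            vals = rng.random((n, n)) * 10
            vals = (vals + vals.T) / 2
            np.fill_diagonal(vals, 0.0)
            labels = [chr(65 + i) for i in range(n)]
            m = DistanceMatrix(labels, vals)
            mine = collect_clades(upgma(m))
            ref = brute_force_upgma(labels, vals)
            assert set(mine) == set(ref)
            for clade, h in ref.items():
                assert mine[clade] == pytest.approx(h)

    def test_ultrametric_input_recovered(self):
        # tree ((A:1,B:1):2,(C:2,D:2):1); distances: AB=2, CD=4, cross=6
        vals = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float)
        tree = upgma(DistanceMatrix(["A", "B", "C", "D"], vals))
        clades = collect_clades(tree)
        assert clades[frozenset("AB")] == pytest.approx(1.0)
        assert clades[frozenset("CD")] == pytest.approx(2.0)
        assert clades[frozenset("ABCD")] == pytest.approx(3.0)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(11)
        vals = rng.random((6, 6)) * 5
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        tree = upgma(DistanceMatrix(list("ABCDEF"), vals))

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)

        check(tree)

    def test_rejects_nan_and_negative(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestPCoA:
    def test_two_points(self):
        m = DistanceMatrix(["a", "b"], np.array([[0, 4], [4, 0]], dtype=float))
        res = pcoa(m)
        assert sorted(res.coordinates[:, 0].tolist()) == pytest.approx([-2.0, 2.0])
        assert res.eigenvalues[0] == pytest.approx(8.0)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_euclidean_recovery(self):
        rng = np.random.default_rng(12)
        pts = rng.random((5, 2)) * 10
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(5)], d))
        rec = np.sqrt(
            ((res.coordinates[:, None, :] - res.coordinates[None, :, :]) ** 2).sum(-1)
        )
        assert np.abs(rec - d).max() < 1e-9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"p{i}" for i in range(6)]
        res1 = pcoa(DistanceMatrix(labels, d))
        perm = rng.permutation(6)
        res2 = pcoa(DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)]))
        # distances between rows are permutation-equivariant even if axes flip
        rec1 = ((res1.coordinates[:, None] - res1.coordinates[None]) ** 2).sum(-1)
        rec2 = ((res2.coordinates[:, None] - res2.coordinates[None]) ** 2).sum(-1)
        assert np.allclose(rec1[np.ix_(perm, perm)], rec2, atol=1e-9)

    def test_eigenvalue_sum_equals_trace(self):
        rng = np.random.default_rng(14)
        vals = rng.random((5, 5)) * 3
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        m = DistanceMatrix([f"p{i}" for i in range(5)], vals)
        res = pcoa(m)
        n = 5
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (vals**2) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b))

    def test_all_zero_matrix(self):
        m = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(m)
        assert np.allclose(res.coordinates, 0.0)


class TestFstSummary:
    def test_single_pair(self):
        s = fst_distribution_summary(np.array([0.4]))
        assert s["min"] == s["max"] == s["mean"] == 0.4

    def test_two_values(self):
        s = fst_distribution_summary(np.array([0.2, 0.4]))
        assert s["mean"] == pytest.approx(0.3)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(15)
        vals = rng.random(10)
        s = fst_distribution_summary(vals)
        assert s["min"] == pytest.approx(vals.min())
        assert s["max"] == pytest.approx(vals.max())
        assert s["mean"] == pytest.approx(vals.mean())
        assert s["sd"] == pytest.approx(vals.std(ddof=1))

    def test_accepts_distance_matrix(self):
        m = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, .1, .3], [.1, 0, .5], [.3, .5, 0]]))
        s = fst_distribution_summary(m)
        assert s["mean"] == pytest.approx(0.3)
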