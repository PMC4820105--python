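import numpy as np
import pandas as pd
import pytest

from bandpop.distance import (
    EARTH_RADIUS_KM,
    bootstrap_support,
    build_tree,
    geographic_distance,
    mantel_test,
    rousset_linearize,
)
from bandpop.matrix import PopulationTable


def _pt(rows):
    return PopulationTable(pd.DataFrame(rows, columns=["population", "latitude", "longitude"]))


def _dm(values, labels):
    return pd.DataFrame(values, index=labels, columns=labels)


class TestLinearize:
    def test_closed_forms(self):
        d = _dm([[0, 0.5], [0.5, 0]], ["a", "b"])
        out = rousset_linearize(d)
        assert out.iloc[0, 1] == pytest.approx(1.0)
        zero = rousset_linearize(_dm([[0, 0], [0, 0]], ["a", "b"]))
        assert zero.iloc[0, 1] == 0.0

    def test_unit_theta_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            rousset_linearize(_dm([[0, 1.0], [1.0, 0]], ["a", "b"]))


class TestGeographicDistance:
    def test_identical_points(self):
        t = _pt([("a", 10.0, 20.0), ("b", 10.0, 20.0)])
        assert geographic_distance(t).iloc[0, 1] == 0.0

    def test_one_degree_of_latitude(self):
        t = _pt([("a", 0.0, 0.0), ("b", 1.0, 0.0)])
        assert geographic_distance(t).iloc[0, 1] == pytest.approx(
            2 * np.pi * EARTH_RADIUS_KM / 360, rel=1e-6
        )

    def test_antipodal_points(self):
        t = _pt([("a", 0.0, 0.0), ("b", 0.0, 180.0)])
        assert geographic_distance(t).iloc[0, 1] == pytest.approx(
            np.pi * EARTH_RADIUS_KM, rel=1e-9
        )


class TestMantel:
    def _matched_matrices(self, n=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        lat_lon = [(0.0, 3.0 * k + 1.0) for k in range(n)]
        t = _pt([(f"p{k}", la, lo) for k, (la, lo) in enumerate(lat_lon)])
        geo = geographic_distance(t)
        g = np.log(np.where(geo > 0, geo, 1.0)) * 0.01
        g += noise * rng.random(g.shape)
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0.0)
        return pd.DataFrame(g, index=geo.index, columns=geo.columns), geo

    def test_proportional_matrices_give_r_one(self):
        gen, geo = self._matched_matrices()
        res = mantel_test(gen, geo, n_perm=200, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-9)
        assert res.p <= 0.05

    def test_affine_invariance(self):
        gen, geo = self._matched_matrices(noise=0.5, seed=3)
        r1 = mantel_test(gen, geo, n_perm=50, seed=2).r
        r2 = mantel_test(gen * 7.0 + 0.0, geo, n_perm=50, seed=2).r
        scaled_geo = geo * 3.0
        r3 = mantel_test(gen, scaled_geo, n_perm=50, seed=2).r
        assert r1 == pytest.approx(r2, abs=1e-12)
        # log(3d) = log 3 + log d: an affine change of the regressor
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        gen, geo = self._matched_matrices(noise=0.8, seed=5)
        ours = mantel_test(gen, geo, n_perm=100, log_transform=False, seed=1)
        theirs, _, _ = skbio_mantel(
            DistanceMatrix(gen.to_numpy(), ids=list(gen.index)),
            DistanceMatrix(geo.to_numpy(), ids=list(geo.index)),
            method="pearson", permutations=0,
        )
        assert ours.r == pytest.approx(float(theirs), abs=1e-12)

    def test_zero_distance_with_log_names_pair(self):
        gen, geo = self._matched_matrices()
        geo.iloc[0, 1] = geo.iloc[1, 0] = 0.0
        with pytest.raises(ValueError, match="p0.*p1"):
            mantel_test(gen, geo, n_perm=10, seed=0)

    def test_seed_determinism(self):
        gen, geo = self._matched_matrices(noise=0.5, seed=7)
        a = mantel_test(gen, geo, n_perm=500, seed=4)
        b = mantel_test(gen, geo, n_perm=500, seed=4)
        assert (a.r, a.p) == (b.r, b.p)


class TestBuildTree:
    def test_hand_agglomeration(self):
        d = _dm([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]], list("ABC"))
        t = build_tree(d, "upgma")
        assert t.to_newick(include_support=False) == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_tie_broken_lexicographically(self):
        d = _dm(np.ones((3, 3)) - np.eye(3), ["C", "A", "B"])
        t = build_tree(d, "upgma")
        assert t.to_newick(include_support=False).startswith("((A:0.5,B:0.5)")

    def test_ultrametric_input_recovered_exactly(self):
        # heights: (A,B) at 0.1; ((A,B),C) at 0.25; root with D at 0.4
        d = _dm(
            [[0, 0.2, 0.5, 0.8],
             [0.2, 0, 0.5, 0.8],
             [0.5, 0.5, 0, 0.8],
             [0.8, 0.8, 0.8, 0]],
            list("ABCD"),
        )
        t = build_tree(d, "upgma")
        tips = {tip.name: tip for tip in t.tree.tips()}
        assert tips["A"].distance(tips["B"]) == pytest.approx(0.2)
        assert tips["A"].distance(tips["C"]) == pytest.approx(0.5)
        assert tips["A"].distance(tips["D"]) == pytest.approx(0.8)

    def test_upgma_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(12)
        X = rng.random((7, 9))
        dm = squareform(pdist(X))
        labels = [f"t{i}" for i in range(7)]
        t = build_tree(_dm(dm, labels), "upgma")
        coph_scipy = squareform(cophenet(linkage(squareform(dm), method="average")))
        tips = {tip.name: tip for tip in t.tree.tips()}
        ours = np.array(
            [[0 if i == j else tips[labels[i]].distance(tips[labels[j]])
              for j in range(7)] for i in range(7)]
        )
        assert np.abs(ours - coph_scipy).max() < 1e-8

    def test_upgma_is_ultrametric(self):
        rng = np.random.default_rng(13)
        X = rng.random((8, 12))
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(X))
        t = build_tree(_dm(dm, [f"t{i}" for i in range(8)]), "upgma")
        depths = t.root_leaf_depths()
        assert np.ptp(depths) / depths.mean() < 1e-9

    def test_asymmetric_matrix_rejected(self):
        d = _dm([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]], list("ABC"))
        with pytest.raises(ValueError, match="symmetric"):
            build_tree(d)

    def test_nj_has_all_leaves(self):
        d = _dm([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]], list("ABC"))
        t = build_tree(d, "nj")
        assert sorted(t.leaves()) == ["A", "B", "C"]


class TestBootstrapSupport:
    def test_clear_split_gets_full_support(self):
        """Two strongly separated population clusters."""
        rng = np.random.default_rng(20)
        qs = {"A": 0.1, "B": 0.12, "C": 0.85, "D": 0.88}
        rows, pops = [], []
        for pop, q in qs.items():
            rows.append((rng.random((12, 60)) > q).astype(np.int8))
            pops += [pop] * 12
        from bandpop.matrix import BandMatrix

        m = BandMatrix([f"i{k}" for k in range(48)], pops,
                       [f"L{j}" for j in range(60)], np.vstack(rows))
        t = bootstrap_support(m, "upgma", n_boot=100, seed=2)
        key = frozenset({"C", "D"})
        assert t.support[key] > 95

    def test_seed_determinism(self, island_matrix):
        m, _ = island_matrix
        t1 = bootstrap_support(m, "upgma", n_boot=50, seed=3)
        t2 = bootstrap_support(m, "upgma", n_boot=50, seed=3)
        assert t1.support == t2.support
        assert t1.to_newick() == t2.to_newick()

    def test_newick_carries_support_labels(self, island_matrix):
        m, _ = island_matrix
        t = bootstrap_support(m, "upgma", n_boot=20, seed=4)
        import re

        assert re.search(r"\)\d+:", t.to_newick())
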