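import numpy as np
import pytest

from bandpop.amova import amova_hierarchical, amova_one_level, band_distance_matrix
from bandpop.matrix import BandMatrix, GroupAssignment
from bandpop.simulate import simulate_island


def _matrix(rows, pops, n_loci=None):
    data = np.asarray(rows, dtype=np.int8)
    return BandMatrix([f"i{k}" for k in range(len(rows))], pops,
                      [f"L{j}" for j in range(data.shape[1])], data)


class TestBandDistance:
    def test_identical_rows_zero(self):
        m = _matrix([[1, 0, 1], [1, 0, 1]], ["A", "A"])
        assert band_distance_matrix(m)[0, 1] == 0.0

    def test_mismatch_count(self):
        m = _matrix([[1, 0, 1], [0, 1, 1]], ["A", "A"])
        assert band_distance_matrix(m)[0, 1] == 2.0

    def test_complementary_rows_maximal(self):
        m = _matrix([[1, 1, 1, 1], [0, 0, 0, 0]], ["A", "A"])
        assert band_distance_matrix(m)[0, 1] == 4.0


class TestOneLevel:
    def test_table_accounting(self, island_matrix):
        m, _ = island_matrix
        res = amova_one_level(m, n_perm=50, seed=1)
        t = res.table
        assert t["df"].iloc[-1] == m.n_individuals - 1
        assert t["df"].iloc[:-1].sum() == t["df"].iloc[-1]
        assert t["SS"].iloc[:2].sum() == pytest.approx(t["SS"].iloc[2])
        assert t["pct"].iloc[:2].sum() == pytest.approx(100.0)

    def test_distance_ss_equals_per_locus_anova_ss(self, island_matrix):
        """Oracle: squared-distance SS equals summed per-locus ANOVA SS."""
        m, _ = island_matrix
        res = amova_one_level(m, n_perm=0, seed=0)
        X = m.data.astype(float)
        ss_total = ((X - X.mean(axis=0)) ** 2).sum()
        ss_within = 0.0
        for p in m.population_names:
            B = X[m.rows_of(p)]
            ss_within += ((B - B.mean(axis=0)) ** 2).sum()
        assert res.table["SS"].iloc[2] == pytest.approx(ss_total)
        assert res.table["SS"].iloc[1] == pytest.approx(ss_within)

    def test_fixed_between_population_difference(self):
        rows = [[1, 1, 1, 1]] * 5 + [[0, 0, 0, 0]] * 5
        m = _matrix(rows, ["A"] * 5 + ["B"] * 5)
        res = amova_one_level(m, n_perm=20, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.table["pct"].iloc[0] == pytest.approx(100.0)

    def test_null_data_gives_small_phi_and_calibrated_p(self):
        rng = np.random.default_rng(3)
        phis, ps = [], []
        for rep in range(15):
            data = (rng.random((40, 30)) < 0.5).astype(np.int8)
            m = _matrix(data, ["A"] * 20 + ["B"] * 20)
            res = amova_one_level(m, n_perm=99, seed=rep)
            phis.append(res.phi_st)
            ps.append(res.p_values["phi_st"])
        assert abs(np.mean(phis)) < 0.02
        assert 0.2 < np.mean(ps) < 0.8  # p roughly uniform under the null

    def test_p_value_bounds(self, island_matrix):
        m, _ = island_matrix
        res = amova_one_level(m, n_perm=49, seed=2)
        assert 1 / 50 <= res.p_values["phi_st"] <= 1.0

    def test_duplicating_individuals_nearly_preserves_phi(self, island_matrix):
        """Exact duplicates change Phi only through finite-sample df terms."""
        m, _ = island_matrix
        m2 = BandMatrix(
            [i + "_a" for i in m.individuals] + [i + "_b" for i in m.individuals],
            list(m.populations) * 2, list(m.loci), np.vstack([m.data, m.data]),
        )
        phi1 = amova_one_level(m, n_perm=0, seed=0).phi_st
        phi2 = amova_one_level(m2, n_perm=0, seed=0).phi_st
        assert phi2 == pytest.approx(phi1, abs=0.02)


class TestHierarchical:
    def _grouped_matrix(self):
        """Two clearly distinct groups of two similar populations each."""
        rng = np.random.default_rng(7)
        qs = {"A": 0.15, "B": 0.2, "C": 0.8, "D": 0.85}  # AB vs CD split
        rows, pops = [], []
        for pop, q in qs.items():
            block = (rng.random((10, 40)) > q).astype(np.int8)
            rows.append(block)
            pops += [pop] * 10
        m = BandMatrix([f"i{k}" for k in range(40)], pops,
                       [f"L{j}" for j in range(40)], np.vstack(rows))
        ga = GroupAssignment({"A": "g1", "B": "g1", "C": "g2", "D": "g2"})
        return m, ga

    def test_components_and_phi_relationships(self):
        m, ga = self._grouped_matrix()
        res = amova_hierarchical(m, ga, n_perm=100, seed=1)
        t = res.table
        assert t["df"].iloc[-1] == 39
        assert t["SS"].iloc[:3].sum() == pytest.approx(t["SS"].iloc[3])
        assert t["pct"].iloc[:3].sum() == pytest.approx(100.0)
        # the dominant split is between the groups
        assert res.phi["phi_ct"] > 0.4
        assert res.p_values["phi_ct"] <= 0.5  # only 3 distinct pop-to-group relabelings
        assert res.p_values["phi_st"] == pytest.approx(1 / 101, abs=1e-9)

    def test_hand_computed_sums_of_squares(self):
        """Brute-force pairwise-distance sums on a six-individual example."""
        rows = [[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 1, 0], [1, 1, 1], [0, 0, 1]]
        pops = ["A", "A", "B", "B", "C", "C"]
        m = _matrix(rows, pops)
        ga = GroupAssignment({"A": "g1", "B": "g1", "C": "g2"})
        res = amova_hierarchical(m, ga, n_perm=10, seed=0)
        X = np.asarray(rows, dtype=float)

        def ss(idx):
            d = 0.0
            for i in idx:
                for j in idx:
                    d += ((X[i] - X[j]) ** 2).sum()
            return d / (2 * len(idx))

        ss_total = ss(range(6))
        ss_wp = ss([0, 1]) + ss([2, 3]) + ss([4, 5])
        ss_wg = ss([0, 1, 2, 3]) + ss([4, 5])
        t = res.table.set_index("source")["SS"]
        assert t["within_populations"] == pytest.approx(ss_wp)
        assert t["among_populations_within_groups"] == pytest.approx(ss_wg - ss_wp)
        assert t["among_groups"] == pytest.approx(ss_total - ss_wg)

    def test_one_population_per_group_empties_middle_stratum(self):
        m, _ = simulate_island(K=3, N=8, L=20, theta_true=0.2, seed=5)
        ga = GroupAssignment({p: f"g{i}" for i, p in enumerate(m.population_names)})
        res = amova_hierarchical(m, ga, n_perm=20, seed=1)
        t = res.table.set_index("source")
        assert t.loc["among_populations_within_groups", "VC"] == 0.0
        assert t.loc["among_populations_within_groups", "df"] == 0

    def test_single_group_falls_back(self, island_matrix):
        m, _ = island_matrix
        ga = GroupAssignment({p: "all" for p in m.population_names})
        with pytest.warns(UserWarning, match="one-level"):
            res = amova_hierarchical(m, ga, n_perm=20, seed=1)
        assert set(res.phi) == {"phi_st"}
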