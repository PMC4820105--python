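"""Analysis of molecular variance (AMOVA) on binary band profiles.

AMOVA partitions the sum of squared pairwise distances between
individual phenotype vectors into hierarchical variance components,
without estimating allele frequencies or assuming Hardy-Weinberg
proportions.  For 0/1 band profiles the natural metric is the mismatch
count, which equals the squared Euclidean distance.  Significance is
assessed by permuting units at the level appropriate to each component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import BandMatrix, GroupAssignment

__all__ = [
    "AmovaResult",
    "band_distance_matrix",
    "amova_one_level",
    "amova_hierarchical",
]


def band_distance_matrix(m: BandMatrix) -> np.ndarray:
    """Squared Euclidean (mismatch-count) distances between individuals."""
    X = m.data.astype(np.float64)
    if (m.data == -1).any():
        raise ValueError("matrix contains missing values")
    # |x-y|^2 = sum of mismatches for 0/1 vectors
    G = X @ X.T
    sq = np.diag(G)
    D2 = sq[:, None] + sq[None, :] - 2 * G
    np.fill_diagonal(D2, 0.0)
    return np.maximum(D2, 0.0)


@dataclass
class AmovaResult:
    """AMOVA table, Phi statistics and permutation p-values."""

    table: pd.DataFrame  # rows: strata + total; columns df, SS, VC, pct
    phi: dict[str, float]  # phi_st (+ phi_ct, phi_sc when hierarchical)
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    negative_components: bool = False

    @property
    def phi_st(self) -> float:
        return self.phi["phi_st"]


def _ss_within_groups(D2: np.ndarray, groups: list[np.ndarray]) -> float:
    """Sum over groups of (sum of within-group squared distances) / n_g."""
    total = 0.0
    for idx in groups:
        if len(idx) > 1:
            total += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return total


def _pop_indices(populations: list[str]) -> dict[str, np.ndarray]:
    out: dict[str, list[int]] = {}
    for i, p in enumerate(populations):
        out.setdefault(p, []).append(i)
    return {p: np.asarray(ix) for p, ix in out.items()}


def _one_level_components(
    D2: np.ndarray, pop_idx: list[np.ndarray]
) -> tuple[float, float, float, float, float]:
    """(SS_among, SS_within, sigma2_a, sigma2_w, phi_st)."""
    N = D2.shape[0]
    K = len(pop_idx)
    sizes = np.array([len(ix) for ix in pop_idx], dtype=float)
    ss_total = D2.sum() / (2.0 * N)
    ss_within = _ss_within_groups(D2, pop_idx)
    ss_among = ss_total - ss_within
    df_among = K - 1
    df_within = N - K
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (N - (sizes**2).sum() / N) / df_among
    sigma_w = ms_within
    sigma_a = (ss_among / df_among - ms_within) / n0
    total = sigma_a + sigma_w
    phi = sigma_a / total if total != 0 else 0.0
    return ss_among, ss_within, sigma_a, sigma_w, phi


def amova_one_level(
    m: BandMatrix, n_perm: int = 1023, seed: int | None = None
) -> AmovaResult:
    """Among/within-population AMOVA with a permutation test on Phi_ST.

    Sums of squares follow the squared-distance formulation
    (SS_total = sum of all pairwise d^2 / N; within-population SS
    analogous per population); the among component uses the unequal-n
    coefficient.  The null distribution of Phi_ST comes from shuffling
    individuals among populations; p uses (count+1)/(n_perm+1).
    """
    pops = m.population_names
    if len(pops) < 2:
        raise ValueError("need >=2 populations")
    D2 = band_distance_matrix(m)
    idx_map = _pop_indices(m.populations)
    pop_idx = [idx_map[p] for p in pops]
    N, K = m.n_individuals, len(pops)
    ss_among, ss_within, sig_a, sig_w, phi = _one_level_components(D2, pop_idx)

    rng = np.random.default_rng(seed)
    sizes = [len(ix) for ix in pop_idx]
    hits = 0
    order = np.arange(N)
    for _ in range(n_perm):
        rng.shuffle(order)
        groups, start = [], 0
        for s in sizes:
            groups.append(order[start : start + s])
            start += s
        phi_p = _one_level_components(D2, groups)[4]
        if phi_p >= phi - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)

    total_vc = sig_a + sig_w
    table = pd.DataFrame(
        {
            "source": ["among_populations", "within_populations", "total"],
            "df": [K - 1, N - K, N - 1],
            "SS": [ss_among, ss_within, ss_among + ss_within],
            "VC": [sig_a, sig_w, total_vc],
            "pct": [100 * sig_a / total_vc, 100 * sig_w / total_vc, 100.0],
        }
    )
    return AmovaResult(
        table=table,
        phi={"phi_st": phi},
        p_values={"phi_st": p},
        n_permutations=n_perm,
        seed=seed,
        negative_components=bool(sig_a < 0),
    )


def _hier_components(
    D2: np.ndarray,
    pop_idx: list[np.ndarray],
    group_of_pop: list[int],
    n_groups: int,
) -> dict[str, float]:
    """Three-level variance components for populations nested in groups."""
    N = D2.shape[0]
    P = len(pop_idx)
    G = n_groups
    sizes = np.array([len(ix) for ix in pop_idx], dtype=float)
    group_idx = [
        np.concatenate([pop_idx[p] for p in range(P) if group_of_pop[p] == g])
        for g in range(G)
    ]
    g_sizes = np.array([len(ix) for ix in group_idx], dtype=float)

    ss_total = D2.sum() / (2.0 * N)
    ss_wp = _ss_within_groups(D2, pop_idx)  # within populations
    ss_wg = _ss_within_groups(D2, group_idx)  # within groups
    ss_ag = ss_total - ss_wg  # among groups
    ss_ap = ss_wg - ss_wp  # among populations within groups

    df_ag = G - 1
    df_ap = P - G
    df_wp = N - P

    # unequal-n coefficients (Excoffier's n, n', n'')
    sum_sq_in_group = np.array(
        [sum(sizes[p] ** 2 for p in range(P) if group_of_pop[p] == g) / g_sizes[g]
         for g in range(G)]
    ).sum()
    n1 = (N - sum_sq_in_group) / df_ap if df_ap > 0 else 0.0
    n2 = (sum_sq_in_group - (sizes**2).sum() / N) / df_ag
    n3 = (N - (g_sizes**2).sum() / N) / df_ag

    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    sig_c = ms_wp
    sig_b = (ss_ap / df_ap - sig_c) / n1 if df_ap > 0 else 0.0
    sig_a = (ss_ag / df_ag - sig_c - n2 * sig_b) / n3

    total = sig_a + sig_b + sig_c
    return {
        "ss_ag": ss_ag, "ss_ap": ss_ap, "ss_wp": ss_wp, "ss_total": ss_total,
        "df_ag": df_ag, "df_ap": df_ap, "df_wp": df_wp,
        "sig_a": sig_a, "sig_b": sig_b, "sig_c": sig_c,
        "phi_ct": sig_a / total if total else 0.0,
        "phi_sc": sig_b / (sig_b + sig_c) if (sig_b + sig_c) else 0.0,
        "phi_st": (sig_a + sig_b) / total if total else 0.0,
    }


def amova_hierarchical(
    m: BandMatrix,
    groups: GroupAssignment,
    n_perm: int = 1023,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA: groups / populations within groups / individuals.

    Permutation schemes per statistic: Phi_CT permutes whole populations
    among groups; Phi_SC permutes individuals among populations within
    their group; Phi_ST permutes individuals among all populations.
    """
    groups.validate(m)
    pops = m.population_names
    group_names = sorted(set(groups.group_of[p] for p in pops))
    if len(group_names) < 2:
        warnings.warn("single group: falling back to one-level AMOVA", stacklevel=2)
        return amova_one_level(m, n_perm=n_perm, seed=seed)
    g_index = {g: i for i, g in enumerate(group_names)}
    group_of_pop = [g_index[groups.group_of[p]] for p in pops]
    D2 = band_distance_matrix(m)
    idx_map = _pop_indices(m.populations)
    pop_idx = [idx_map[p] for p in pops]
    obs = _hier_components(D2, pop_idx, group_of_pop, len(group_names))

    rng = np.random.default_rng(seed)
    hits = {"phi_ct": 0, "phi_sc": 0, "phi_st": 0}
    P = len(pops)
    sizes = [len(ix) for ix in pop_idx]
    for _ in range(n_perm):
        # Phi_CT: permute populations among groups
        perm_assign = list(group_of_pop)
        rng.shuffle(perm_assign)
        c = _hier_components(D2, pop_idx, perm_assign, len(group_names))
        if c["phi_ct"] >= obs["phi_ct"] - 1e-12:
            hits["phi_ct"] += 1
        # Phi_SC: permute individuals among populations within groups
        new_pop_idx: list[np.ndarray] = [None] * P  # type: ignore[list-item]
        for g in range(len(group_names)):
            members = [p for p in range(P) if group_of_pop[p] == g]
            pool = np.concatenate([pop_idx[p] for p in members])
            pool = rng.permutation(pool)
            start = 0
            for p in members:
                new_pop_idx[p] = pool[start : start + sizes[p]]
                start += sizes[p]
        c = _hier_components(D2, new_pop_idx, group_of_pop, len(group_names))
        if c["phi_sc"] >= obs["phi_sc"] - 1e-12:
            hits["phi_sc"] += 1
        # Phi_ST: permute individuals among all populations
        pool = rng.permutation(np.arange(m.n_individuals))
        start = 0
        shuffled = []
        for s in sizes:
            shuffled.append(pool[start : start + s])
            start += s
        c = _hier_components(D2, shuffled, group_of_pop, len(group_names))
        if c["phi_st"] >= obs["phi_st"] - 1e-12:
            hits["phi_st"] += 1
    p_values = {k: (v + 1) / (n_perm + 1) for k, v in hits.items()}

    total = obs["sig_a"] + obs["sig_b"] + obs["sig_c"]
    table = pd.DataFrame(
        {
            "source": [
                "among_groups",
                "among_populations_within_groups",
                "within_populations",
                "total",
            ],
            "df": [obs["df_ag"], obs["df_ap"], obs["df_wp"],
                   obs["df_ag"] + obs["df_ap"] + obs["df_wp"]],
            "SS": [obs["ss_ag"], obs["ss_ap"], obs["ss_wp"], obs["ss_total"]],
            "VC": [obs["sig_a"], obs["sig_b"], obs["sig_c"], total],
            "pct": [
                100 * obs["sig_a"] / total,
                100 * obs["sig_b"] / total,
                100 * obs["sig_c"] / total,
                100.0,
            ],
        }
    )
    return AmovaResult(
        table=table,
        phi={k: obs[k] for k in ("phi_ct", "phi_sc", "phi_st")},
        p_values=p_values,
        n_permutations=n_perm,
        seed=seed,
        negative_components=bool(min(obs["sig_a"], obs["sig_b"], obs["sig_c"]) < 0),
    )
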