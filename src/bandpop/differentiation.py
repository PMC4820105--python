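"""Population differentiation: Weir-Cockerham theta and exact tests.

Theta is the coancestry analogue of Wright's F_ST, estimated from the
among/within-population variance components of allele frequencies.  For
dominant markers genotypes are unobserved, so the per-population allele
frequencies entering the components are the Lynch-Milligan corrected
estimates and the heterozygote frequency term is replaced by its
Hardy-Weinberg expectation 2*p*q.

The exact test of population differentiation treats each locus as a
2 x K contingency table (phenotype x population) and asks how extreme
the observed table is among all tables with the same margins, under the
multivariate hypergeometric null.  Small tables are enumerated; larger
ones are explored with a Metropolis Markov chain over tables.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .diversity import estimate_locus
from .matrix import BandMatrix

__all__ = [
    "ThetaResult",
    "ExactTestResult",
    "wc_theta",
    "theta_resample",
    "pairwise_theta",
    "mcmc_exact_test",
    "exact_test_all",
    "enumerate_exact_test",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _corrected_freqs(m: BandMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Null-allele frequency matrix Q (pops x loci) and sample sizes."""
    pops = m.population_names
    K, L = len(pops), m.n_loci
    Q = np.empty((K, L))
    n = np.empty(K, dtype=float)
    for k, pop in enumerate(pops):
        absent, N = m.absent_counts(pop)
        n[k] = N
        for l in range(L):
            Q[k, l] = estimate_locus(int(absent[l]), N).q
    return Q, n, pops

def _wc_components(Q: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components a (among), b, c (within).

    ``Q`` holds null-allele frequencies per population (rows) and locus
    (columns); ``n`` the per-population sample sizes in individuals.
    Heterozygosity is taken at its HWE expectation 2*p*q.
    """
    r = Q.shape[0]
    if r < 2:
        raise ValueError("need >=2 populations")
    p = 1.0 - Q
    h = 2.0 * p * Q
    n = np.asarray(n, dtype=float)
    n_tot = n.sum()
    nbar = n.mean()
    nc = (n_tot - (n**2).sum() / n_tot) / (r - 1)
    w = n[:, None] / n_tot
    pbar = (w * p).sum(axis=0)
    s2 = (n[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (w * h).sum(axis=0)

    inner = pbar * (1.0 - pbar) - (r - 1) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c = hbar / 2.0
    return a, b, c


@dataclass
class ThetaResult:
    """Multi-locus theta with optional resampling uncertainty."""

    theta: float
    loci: list[str]
    a: np.ndarray  # among-population component per locus
    d: np.ndarray  # total a+b+c per locus
    used: np.ndarray  # loci contributing (a+b+c != 0)
    jackknife_mean: float | None = None
    jackknife_se: float | None = None
    bootstrap_ci95: tuple[float, float] | None = None
    n_bootstrap: int = 0
    seed: int | None = None

    @property
    def n_loci_used(self) -> int:
        return int(self.used.sum())


def wc_theta(m: BandMatrix) -> ThetaResult:
    """Multi-locus Weir-Cockerham theta over all populations.

    Theta is the ratio of summed per-locus components sum(a)/sum(a+b+c);
    negative per-locus components are retained in the sums.  Loci that
    are monomorphic in every population contribute zero to both sums and
    are flagged as unused.
    """
    Q, n, _ = _corrected_freqs(m)
    a, b, c = _wc_components(Q, n)
    d = a + b + c
    used = np.abs(d) > 1e-14
    if not used.any():
        raise ValueError("every locus monomorphic; theta undefined")
    theta = float(a[used].sum() / d[used].sum())
    return ThetaResult(theta=theta, loci=list(m.loci), a=a, d=d, used=used)


def theta_resample(
    m: BandMatrix, n_bootstrap: int = 5000, seed: int | None = None
) -> ThetaResult:
    """Delete-one-locus jackknife and percentile bootstrap for theta."""
    res = wc_theta(m)
    a = res.a[res.used]
    d = res.d[res.used]
    L = len(a)
    if L < 2:
        raise ValueError("resampling needs >=2 informative loci")
    A, D = a.sum(), d.sum()
    loo = (A - a) / (D - d)
    jk_mean = float(loo.mean())
    jk_se = float(np.sqrt((L - 1) / L * ((loo - jk_mean) ** 2).sum()))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, L, size=(n_bootstrap, L))
    boot = a[idx].sum(axis=1) / d[idx].sum(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    res.jackknife_mean = jk_mean
    res.jackknife_se = jk_se
    res.bootstrap_ci95 = (float(lo), float(hi))
    res.n_bootstrap = n_bootstrap
    res.seed = seed
    return res


def pairwise_theta(m: BandMatrix) -> pd.DataFrame:
    """Symmetric matrix of two-population theta estimates."""
    Q, n, pops = _corrected_freqs(m)
    K = len(pops)
    out = np.zeros((K, K))
    for i, j in combinations(range(K), 2):
        a, b, c = _wc_components(Q[[i, j]], n[[i, j]])
        d = a + b + c
        used = np.abs(d) > 1e-14
        th = float(a[used].sum() / d[used].sum()) if used.any() else 0.0
        out[i, j] = out[j, i] = th
    return pd.DataFrame(out, index=pops, columns=pops)


def pairwise_locus_components(
    m: BandMatrix,
) -> tuple[list[str], dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]]:
    """Per-locus (a, a+b+c) arrays for every population pair.

    Components are additive over loci, so locus-bootstrap replicates of
    any pairwise theta reduce to resampled sums of these arrays.
    """
    Q, n, pops = _corrected_freqs(m)
    comps: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for i, j in combinations(range(len(pops)), 2):
        a, b, c = _wc_components(Q[[i, j]], n[[i, j]])
        comps[(pops[i], pops[j])] = (a, a + b + c)
    return pops, comps


# ---------------------------------------------------------------------------
# Exact test of population differentiation
# ---------------------------------------------------------------------------


@dataclass
class ExactTestResult:
    """Markov-chain exact-test p-value for one locus."""

    locus: str
    p: float
    se: float
    batch_p: list[float] = field(default_factory=list)
    monomorphic: bool = False


def _locus_table(m: BandMatrix, locus: str) -> np.ndarray:
    j = m.loci.index(locus)
    pops = m.population_names
    table = np.zeros((2, len(pops)), dtype=np.int64)
    for k, pop in enumerate(pops):
        col = m.data[m.rows_of(pop), j]
        table[0, k] = int((col == 1).sum())  # band present
        table[1, k] = int((col == 0).sum())  # band absent
    return table


def _table_logprob_terms(table: np.ndarray) -> float:
    return float(-gammaln(table + 1.0).sum())


def mcmc_exact_test(
    m: BandMatrix,
    locus: str,
    dememorization: int = 1000,
    batches: int = 10,
    perms_per_batch: int = 2000,
    seed: int | None = None,
) -> ExactTestResult:
    """Markov-chain exact test of allele-frequency homogeneity at a locus.

    The chain walks the space of 2 x K tables with the observed margins
    using uniform +/-1 swaps on random 2 x 2 sub-tables, accepted by the
    Metropolis rule under the conditional (multivariate hypergeometric)
    distribution.  The p-value is the fraction of visited tables whose
    conditional probability does not exceed the observed one, estimated
    per batch to give a standard error.
    """
    table = _locus_table(m, locus)
    if (table.sum(axis=1) == 0).any():
        return ExactTestResult(locus, 1.0, 0.0, monomorphic=True)
    K = table.shape[1]
    rng = random.Random(seed)
    N = int(table.sum())
    logfact = gammaln(np.arange(N + 2) + 1.0)

    t = [list(map(int, row)) for row in table]
    logp = -sum(logfact[v] for row in t for v in row)
    logp_obs = logp + 1e-9

    def step() -> float:
        nonlocal logp
        j1 = rng.randrange(K)
        j2 = rng.randrange(K - 1)
        if j2 >= j1:
            j2 += 1
        d = 1 if rng.random() < 0.5 else -1
        a0, b0 = t[0][j1], t[0][j2]
        a1, b1 = t[1][j1], t[1][j2]
        na0, nb0, na1, nb1 = a0 + d, b0 - d, a1 - d, b1 + d
        if min(na0, nb0, na1, nb1) < 0:
            return logp
        delta = (
            logfact[a0] + logfact[b0] + logfact[a1] + logfact[b1]
            - logfact[na0] - logfact[nb0] - logfact[na1] - logfact[nb1]
        )
        if delta >= 0 or rng.random() < math.exp(delta):
            t[0][j1], t[0][j2], t[1][j1], t[1][j2] = na0, nb0, na1, nb1
            logp += delta
        return logp

    for _ in range(dememorization):
        step()
    batch_p = []
    for _ in range(batches):
        hits = 0
        for _ in range(perms_per_batch):
            if step() <= logp_obs:
                hits += 1
        batch_p.append(hits / perms_per_batch)
    p = float(np.mean(batch_p))
    se = float(np.std(batch_p, ddof=1) / math.sqrt(batches)) if batches > 1 else 0.0
    return ExactTestResult(locus, p, se, batch_p)


def exact_test_all(
    m: BandMatrix,
    dememorization: int = 1000,
    batches: int = 10,
    perms_per_batch: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact test at every locus; one independent chain per locus.

    Returns a per-locus table of p-values and flags; the count of loci
    significant at ``alpha`` is in ``df.attrs["n_significant"]``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(m.n_loci)
    rows = []
    for l, s in zip(m.loci, seeds):
        r = mcmc_exact_test(m, l, dememorization, batches, perms_per_batch, int(s))
        rows.append(
            {"locus": l, "p": r.p, "se": r.se, "monomorphic": r.monomorphic,
             "significant": (not r.monomorphic) and r.p < alpha}
        )
    df = pd.DataFrame(rows)
    df.attrs["n_significant"] = int(df["significant"].sum())
    df.attrs["alpha"] = alpha
    return df


def enumerate_exact_test(table: np.ndarray) -> float:
    """Exact differentiation p by full enumeration of a 2 x K table.

    Sums the conditional probabilities of every table sharing the
    observed margins whose probability is <= that of the observed table.
    Guarded against combinatorial blow-up (<= 1e6 candidate tables).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.shape[0] != 2:
        raise ValueError("expected a 2 x K table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any():
        return 1.0
    bound = np.prod([min(int(c), int(row[0])) + 1 for c in col], dtype=float)
    if bound > 1e6:
        raise ValueError(f"~{bound:.0f} candidate tables; use the Markov-chain test")
    N = int(table.sum())
    logfact = gammaln(np.arange(N + 1) + 1.0)
    log_margin = float(logfact[row].sum() + logfact[col].sum() - logfact[N])
    K = table.shape[1]

    obs_logp = log_margin - float(logfact[table].sum())
    total_le = 0.0

    first = np.empty(K, dtype=np.int64)

    def recurse(j: int, remaining: int, partial: float) -> None:
        nonlocal total_le
        if j == K - 1:
            if remaining > col[j]:
                return
            t0 = remaining
            t1 = col[j] - t0
            logp = partial - logfact[t0] - logfact[t1]
            if logp <= obs_logp + 1e-9:
                total_le += math.exp(logp)
            return
        lo = max(0, remaining - int(col[j + 1:].sum()))
        hi = min(int(col[j]), remaining)
        for t0 in range(lo, hi + 1):
            t1 = col[j] - t0
            recurse(j + 1, remaining - t0, partial - logfact[t0] - logfact[t1])

    recurse(0, int(row[0]), log_margin)
    return min(1.0, float(total_le))
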