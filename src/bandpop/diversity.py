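"""Lynch-Milligan diversity statistics for dominant markers.

A dominant locus shows a band for genotypes AA and Aa and no band for
the null homozygote aa.  Under Hardy-Weinberg proportions the
band-absence phenotype frequency x estimates q^2, so the naive estimate
of the null-allele frequency is sqrt(x).  That estimator is biased
upward for small samples; Lynch & Milligan's Taylor-series correction

    q = sqrt(x) * [1 - Var(x) / (8 x^2)]^(-1),   Var(x) = x(1-x)/N

removes the leading-order bias, and the per-locus gene diversity is

    He = 2 q (1-q) + 2 Var(q),   Var(q) = (1-x)/(4N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import BandMatrix

__all__ = [
    "LocusEstimate",
    "PopulationDiversity",
    "estimate_locus",
    "locus_estimates",
    "population_diversity",
    "species_diversity",
    "percent_polymorphic",
]


@dataclass
class LocusEstimate:
    """Corrected allele-frequency estimate at one dominant locus."""

    locus: str
    N: int
    x: float  # band-absence phenotype frequency
    var_x: float
    q: float  # null-allele frequency, bias-corrected
    var_q: float
    he: float
    x_zero: bool = False  # correction undefined at x = 0; q set to 0

    @property
    def p(self) -> float:
        return 1.0 - self.q


def estimate_locus(absent_count: int, N: int, locus: str = "") -> LocusEstimate:
    """Bias-corrected q, Var(q) and He from a band-absence count.

    At x = 0 the correction factor divides by x^2 and is undefined; such
    loci are reported with q = 0 and He = 2 Var(q), and flagged.  The
    corrected q is clamped to [0, 1] (the correction can push it past 1
    when x is close to 1 in a small sample).
    """
    if not 0 <= absent_count <= N:
        raise ValueError(f"absent_count {absent_count} outside [0, {N}]")
    if N < 1:
        raise ValueError("N must be >= 1")
    x = absent_count / N
    var_x = x * (1.0 - x) / N
    var_q = (1.0 - x) / (4.0 * N)
    if absent_count == 0:
        return LocusEstimate(locus, N, x, var_x, 0.0, var_q, 2.0 * var_q, x_zero=True)
    q = np.sqrt(x) / (1.0 - var_x / (8.0 * x * x))
    q = float(np.clip(q, 0.0, 1.0))
    he = 2.0 * q * (1.0 - q) + 2.0 * var_q
    return LocusEstimate(locus, N, x, var_x, q, var_q, he)


def locus_estimates(m: BandMatrix, population: str | None = None) -> list[LocusEstimate]:
    """Per-locus estimates for one population (or the pooled sample)."""
    absent, N = m.absent_counts(population)
    return [estimate_locus(int(a), N, locus=l) for a, l in zip(absent, m.loci)]


def percent_polymorphic(estimates: list[LocusEstimate], criterion: float = 0.95) -> float:
    """Percentage of loci polymorphic under the frequency criterion.

    A locus counts as polymorphic when its most common allele is at
    frequency <= ``criterion`` (the standard 95% rule).
    """
    if not estimates:
        raise ValueError("no locus estimates")
    poly = sum(1 for e in estimates if max(e.p, e.q) <= criterion + 1e-12)
    return 100.0 * poly / len(estimates)


@dataclass
class PopulationDiversity:
    """Mean expected heterozygosity and polymorphism of one sample."""

    population: str
    N: int
    n_loci: int
    h: float  # mean He over loci (H_pop, or H_sp for the pooled sample)
    se_h: float  # SE of that mean, over loci
    pct_polymorphic: float
    estimates: list[LocusEstimate]

    def summary_row(self) -> dict:
        return {
            "population": self.population,
            "N": self.N,
            "n_loci": self.n_loci,
            "H": self.h,
            "SE": self.se_h,
            "pct_polymorphic": self.pct_polymorphic,
        }


def _summarise(estimates: list[LocusEstimate], label: str, N: int) -> PopulationDiversity:
    he = np.array([e.he for e in estimates])
    se = float(he.std(ddof=1) / np.sqrt(len(he))) if len(he) > 1 else 0.0
    return PopulationDiversity(
        population=label,
        N=N,
        n_loci=len(estimates),
        h=float(he.mean()),
        se_h=se,
        pct_polymorphic=percent_polymorphic(estimates),
        estimates=estimates,
    )


def population_diversity(m: BandMatrix, population: str) -> PopulationDiversity:
    """H_pop +/- SE and %P for one population sample."""
    ests = locus_estimates(m, population)
    N = m.population_sizes()[population]
    return _summarise(ests, population, N)


def species_diversity(m: BandMatrix) -> PopulationDiversity:
    """H_sp +/- SE and %P with every individual pooled into one sample."""
    ests = locus_estimates(m, None)
    return _summarise(ests, "pooled", m.n_individuals)


def diversity_table(m: BandMatrix) -> pd.DataFrame:
    """Per-population diversity summary plus a pooled total row."""
    rows = [population_diversity(m, p).summary_row() for p in m.population_names]
    rows.append(species_diversity(m).summary_row())
    return pd.DataFrame(rows)
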