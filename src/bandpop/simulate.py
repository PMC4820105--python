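"""Synthetic dominant-marker datasets with known truth.

The island generator mirrors the hierarchical beta model used for
inference: each locus has an ancestral null-allele frequency pi_l, each
population's frequency q_kl scatters around it as

    q_kl ~ Beta(pi_l (1-theta*)/theta*, (1-pi_l)(1-theta*)/theta*)

so that E[q] = pi and Var(q) = theta* pi (1-pi) -- the defining moment
relation of Wright's F_ST.  Diploid individuals are then null
homozygotes (band absent) with probability q^2 + f q(1-q), i.e.
Hardy-Weinberg proportions with optional inbreeding f, and the dominant
phenotype masks the remaining genotypes as band present.

The stepping-stone generator instead lets frequencies drift along a
linear chain of populations, producing divergence that grows with
coordinate separation -- the isolation-by-distance regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit, logit

from .matrix import BandMatrix

__all__ = ["SimulationTruth", "simulate_island", "simulate_stepping_stone"]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    layout: str  # "island" | "stepping_stone"
    theta_true: float | None
    f: float
    pi: np.ndarray  # per-locus ancestral null-allele frequency
    q: np.ndarray  # populations x loci null-allele frequencies
    seed: int | None
    coordinates: list[tuple[float, float]] | None = None  # (lat, lon) per population

    def mean_heterozygosity(self) -> np.ndarray:
        """True per-population mean 2q(1-q) over loci."""
        return (2.0 * self.q * (1.0 - self.q)).mean(axis=1)

    def to_json(self) -> str:
        d = asdict(self)
        d["pi"] = self.pi.tolist()
        d["q"] = self.q.tolist()
        return json.dumps(d, indent=1)


def _draw_pi(rng: np.random.Generator, L: int, pi_dist) -> np.ndarray:
    """Ancestral frequencies from a (lo, hi) uniform range or beta params."""
    if isinstance(pi_dist, dict):
        return rng.beta(pi_dist["a"], pi_dist["b"], size=L)
    lo, hi = pi_dist
    return rng.uniform(lo, hi, size=L)


def _phenotypes(
    rng: np.random.Generator,
    q: np.ndarray,
    N: np.ndarray,
    f: float,
    names: list[str] | None = None,
) -> tuple[list[str], list[str], np.ndarray]:
    """Sample band phenotypes: absent iff null homozygote."""
    K, L = q.shape
    s = q * q + f * q * (1.0 - q)
    rows, individuals, populations = [], [], []
    for k in range(K):
        name = names[k] if names is not None else f"pop{k + 1}"
        absent = rng.random((int(N[k]), L)) < s[k]
        rows.append(np.where(absent, 0, 1).astype(np.int8))
        individuals += [f"{name}_i{i + 1}" for i in range(int(N[k]))]
        populations += [name] * int(N[k])
    return individuals, populations, np.vstack(rows)


def simulate_island(
    K: int = 8,
    N: int | list[int] = 40,
    L: int = 300,
    theta_true: float = 0.2,
    pi_dist=(0.1, 0.9),
    f: float = 0.0,
    seed: int | None = None,
    population_names: list[str] | None = None,
) -> tuple[BandMatrix, SimulationTruth]:
    """Island-model dominant-marker dataset with controllable true F_ST.

    ``pi_dist`` is either a ``(lo, hi)`` uniform range (default avoids
    loci the high-band-frequency filter would immediately discard) or a
    ``{"a": ..., "b": ...}`` beta parameterisation for a "raw" frequency
    spectrum including extremes.  ``theta_true = 0`` is handled as the
    panmictic limit q_kl = pi_l.
    """
    if not 0.0 <= theta_true < 1.0:
        raise ValueError("theta_true must be in [0, 1)")
    if K < 1:
        raise ValueError("K >= 1 required")
    rng = np.random.default_rng(seed)
    sizes = np.full(K, N, dtype=int) if np.isscalar(N) else np.asarray(N, dtype=int)
    if len(sizes) != K:
        raise ValueError("len(N) must equal K")
    pi = _draw_pi(rng, L, pi_dist)
    if theta_true == 0.0:
        q = np.tile(pi, (K, 1))
    else:
        scale = (1.0 - theta_true) / theta_true
        q = rng.beta(pi * scale, (1.0 - pi) * scale, size=(K, L))
    individuals, populations, data = _phenotypes(rng, q, sizes, f, population_names)
    truth = SimulationTruth(
        layout="island", theta_true=theta_true, f=f, pi=pi, q=q, seed=seed
    )
    loci = [f"L{j + 1}" for j in range(L)]
    return BandMatrix(individuals, populations, loci, data), truth


def simulate_stepping_stone(
    K: int = 8,
    N: int | list[int] = 40,
    L: int = 300,
    neighbor_mix: float = 0.3,
    pi_dist=(0.1, 0.9),
    f: float = 0.0,
    spacing_deg: float = 1.0,
    seed: int | None = None,
) -> tuple[BandMatrix, SimulationTruth]:
    """One-dimensional stepping-stone chain with isolation by distance.

    Frequencies perform a random walk on the logit scale along the
    chain, with per-step standard deviation shrinking as ``neighbor_mix``
    (the homogenising migration weight) grows; ``neighbor_mix -> 1`` is
    the panmictic limit.  Populations sit ``spacing_deg`` degrees of
    longitude apart on the equator, so great-circle distance is linear
    in chain position.
    """
    if K < 3:
        raise ValueError("K >= 3 required for a chain")
    if not 0.0 < neighbor_mix <= 1.0:
        raise ValueError("neighbor_mix in (0, 1] required")
    rng = np.random.default_rng(seed)
    sizes = np.full(K, N, dtype=int) if np.isscalar(N) else np.asarray(N, dtype=int)
    pi = _draw_pi(rng, L, pi_dist)
    sigma = 0.9 * (1.0 - neighbor_mix)
    z = np.empty((K, L))
    z[0] = logit(np.clip(pi, 1e-6, 1 - 1e-6)) + sigma * rng.standard_normal(L)
    for k in range(1, K):
        z[k] = z[k - 1] + sigma * rng.standard_normal(L)
    q = expit(z)
    individuals, populations, data = _phenotypes(rng, q, sizes, f)
    coords = [(0.0, k * spacing_deg) for k in range(K)]
    truth = SimulationTruth(
        layout="stepping_stone", theta_true=None, f=f, pi=pi, q=q,
        seed=seed, coordinates=coords,
    )
    loci = [f"L{j + 1}" for j in range(L)]
    return BandMatrix(individuals, populations, loci, data), truth


def inject_missing_primer_blocks(
    m: BandMatrix,
    primer_of: dict[str, str],
    fraction: float = 0.05,
    seed: int | None = None,
) -> BandMatrix:
    """Blank out whole primer blocks for a random subset of individuals.

    Emulates amplification failure: an affected individual loses every
    locus of one primer, the pattern the incomplete-individual filter is
    designed to remove.
    """
    rng = np.random.default_rng(seed)
    primers = sorted(set(primer_of.values()))
    data = m.data.copy()
    for i in rng.choice(m.n_individuals, max(1, int(fraction * m.n_individuals)), replace=False):
        primer = primers[rng.integers(len(primers))]
        cols = [j for j, l in enumerate(m.loci) if primer_of[l] == primer]
        data[i, cols] = -1
    return BandMatrix(list(m.individuals), list(m.populations), list(m.loci), data)
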