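"""End-to-end orchestration of the dominant-marker analysis.

One configuration drives the full chain: band-frequency filtering,
Lynch-Milligan diversity, Weir-Cockerham theta with resampling, exact
differentiation tests, AMOVA (one-level and, with groups, hierarchical),
the Bayesian f-free model, linearized distances with a Mantel
isolation-by-distance test, and bootstrap-supported trees.  Every
stochastic stage receives its own child seed derived from the master
seed, so a rerun with the same configuration reproduces every output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .amova import amova_hierarchical, amova_one_level
from .bayes import BayesModelSpec, fit_f_free
from .differentiation import exact_test_all, pairwise_theta, theta_resample
from .distance import (
    DistanceSet,
    bootstrap_support,
    geographic_distance,
    mantel_test,
    rousset_linearize,
)
from .diversity import diversity_table
from .matrix import (
    GroupAssignment,
    PopulationTable,
    drop_incomplete_individuals,
    lynch_milligan_filter,
    read_band_matrix,
    read_group_assignment,
    read_population_table,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, resampling counts, MCMC settings and seeds for one run."""

    matrix_path: str | Path
    population_table_path: str | Path | None = None
    groups_path: str | Path | None = None
    output_dir: str | Path = "bandpop_out"
    filter_unit: str | None = "pooled"  # None disables the band-frequency filter
    alpha: float = 0.05
    n_bootstrap: int = 5000
    amova_permutations: int = 1023
    mantel_permutations: int = 10000
    tree_bootstraps: int = 1000
    exact_dememorization: int = 1000
    exact_batches: int = 10
    exact_perms_per_batch: int = 2000
    mcmc_burn_in: int = 5000
    mcmc_samples: int = 25000
    mcmc_thin: int = 5
    mcmc_chains: int = 4
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        stages = [
            "theta", "exact", "amova", "amova_hier", "bayes", "mantel", "tree",
        ]
        ss = np.random.SeedSequence(self.seed).spawn(len(stages))
        return int(ss[stages.index(stage)].generate_state(1)[0] % (2**31))


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict of in-memory results; files mirroring the published
    table shapes (diversity summary, AMOVA table, distance matrices,
    newick trees, exact-test p-values, Mantel report) land in
    ``config.output_dir`` together with a provenance log.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    log: dict = {"config": {k: str(v) for k, v in asdict(config).items()},
                 "version": __version__}

    m = read_band_matrix(config.matrix_path)
    if m.has_missing():
        m, removed = drop_incomplete_individuals(m)
        removed.to_csv(out / "removed_individuals.csv", index=False)
        log["removed_individuals"] = len(removed)
    if config.filter_unit is not None:
        m, report = lynch_milligan_filter(m, config.filter_unit)
        report.excluded.to_csv(out / "excluded_loci.csv", index=False)
        log["excluded_loci"] = len(report.excluded)
    log["n_individuals"] = m.n_individuals
    log["n_loci"] = m.n_loci
    results["matrix"] = m

    pops: PopulationTable | None = None
    if config.population_table_path is not None:
        pops = read_population_table(config.population_table_path)
        pops.check_against(m)
    groups: GroupAssignment | None = None
    if config.groups_path is not None:
        groups = read_group_assignment(config.groups_path)

    # diversity (Lynch-Milligan)
    div = _stage("diversity")(diversity_table)(m)
    div.to_csv(out / "diversity.csv", index=False)
    results["diversity"] = div

    # Weir-Cockerham theta with jackknife + bootstrap
    theta = _stage("theta")(theta_resample)(
        m, n_bootstrap=config.n_bootstrap, seed=config.stage_seed("theta")
    )
    results["theta"] = theta

    # exact differentiation tests
    exact = _stage("exact_test")(exact_test_all)(
        m,
        dememorization=config.exact_dememorization,
        batches=config.exact_batches,
        perms_per_batch=config.exact_perms_per_batch,
        seed=config.stage_seed("exact"),
        alpha=config.alpha,
    )
    exact.to_csv(out / "exact_tests.csv", index=False)
    results["exact"] = exact

    # AMOVA
    amova = _stage("amova")(amova_one_level)(
        m, n_perm=config.amova_permutations, seed=config.stage_seed("amova")
    )
    amova.table.to_csv(out / "amova.csv", index=False)
    results["amova"] = amova
    if groups is not None:
        hier = _stage("amova_hierarchical")(amova_hierarchical)(
            m, groups, n_perm=config.amova_permutations,
            seed=config.stage_seed("amova_hier"),
        )
        hier.table.to_csv(out / "amova_hierarchical.csv", index=False)
        results["amova_hierarchical"] = hier

    # Bayesian f-free model
    spec = BayesModelSpec(
        burn_in=config.mcmc_burn_in,
        n_samples=config.mcmc_samples,
        thin=config.mcmc_thin,
        n_chains=config.mcmc_chains,
        seed=config.stage_seed("bayes"),
    )
    bayes = _stage("bayes")(fit_f_free)(m, spec)
    bayes.h_table.to_csv(out / "bayes_h.csv", index=False)
    results["bayes"] = bayes

    # distances, Mantel, trees
    theta_pair = _stage("pairwise_theta")(pairwise_theta)(m)
    genetic = rousset_linearize(theta_pair)
    genetic.to_csv(out / "genetic_distance.csv")
    results["pairwise_theta"] = theta_pair
    results["genetic_distance"] = genetic
    if pops is not None:
        dset = DistanceSet(
            genetic=genetic,
            geographic_km=_stage("geographic")(geographic_distance)(
                pops, list(genetic.index)
            ),
        )
        dset.geographic_km.to_csv(out / "geographic_km.csv")
        mantel = _stage("mantel")(mantel_test)(
            dset.genetic, dset.geographic_km,
            n_perm=config.mantel_permutations, seed=config.stage_seed("mantel"),
        )
        results["mantel"] = mantel
        (out / "mantel.json").write_text(json.dumps(asdict(mantel), indent=1))

    tree_seed = config.stage_seed("tree")
    for method in ("upgma", "nj"):
        tree = _stage(f"tree_{method}")(bootstrap_support)(
            m, method=method, n_boot=config.tree_bootstraps, seed=tree_seed
        )
        (out / f"tree_{method}.nwk").write_text(tree.to_newick() + "\n")
        results[f"tree_{method}"] = tree

    # headline summary + provenance
    summary = {
        "H_sp": float(div.iloc[-1]["H"]),
        "pct_polymorphic_sp": float(div.iloc[-1]["pct_polymorphic"]),
        "theta": theta.theta,
        "theta_ci95": list(theta.bootstrap_ci95),
        "phi_st": amova.phi_st,
        "theta_bayes_mode": bayes.theta_mode,
        "theta_bayes_hdr": list(bayes.theta_hdr),
        "H_BT": bayes.h_bt_mean,
        "mean_genetic_distance": float(
            genetic.to_numpy()[np.triu_indices(len(genetic), 1)].mean()
        ),
        "n_loci_significant": int(exact.attrs["n_significant"]),
    }
    if "mantel" in results:
        summary["mantel_r"] = results["mantel"].r
        summary["mantel_p"] = results["mantel"].p
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "provenance.json").write_text(json.dumps(log, indent=1))
    results["summary"] = summary
    return results
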