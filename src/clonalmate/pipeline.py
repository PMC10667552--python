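"""End-to-end mate-allocation experiment.

One run: generate (or load) a training population of genotyped and
phenotyped clones; fit the additive-only and extended genomic models;
pick the top parents by GEBV; then, over several iterations, randomly
split the parents into females and males, simulate every factorial
cross, predict each simulated progeny's breeding value (GEBV) and
clonal value (GPCP), score crosses by their top-decile progeny, and
solve the two ILPs — one maximising summed breeding-value merit, one
maximising summed clonal-value merit.  Both strategies are scored on
the *same* simulated progeny within an iteration; only the sex split is
re-randomised across iterations, the parent pool is fixed.  Results are
aggregated as mean (SD) over iterations.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allocation import (
    cross_merit,
    enumerate_crosses,
    select_crosses_ilp,
    strategy_comparison,
    validate_plan,
)
from .containers import GenotypeMatrix, InvalidParameterError
from .meiosis import phase_genotypes, simulate_families
from .models import (
    MMEFit,
    VarianceComponents,
    fit_reml,
    heritability_report,
    likelihood_ratio_test,
    predict_progeny,
)
from .relationships import (
    GRMSet,
    allele_frequencies,
    cross_block_grms,
    genomewide_heterozygosity,
)
from .synthetic import (
    TraitArchitecture,
    generate_founders,
    generate_map,
    generate_trait_architecture,
    genetic_value,
    simulate_phenotypes,
    subset_map,
)

logger = logging.getLogger(__name__)

# Trait presets: (sigma2_A, sigma2_D, sigma2_AA, sigma2_eps) on the trait
# scale plus the genome-wide heterozygosity slope.  "tch" has large
# epistatic and heterozygosity effects; "ccs"/"fibre" have near-zero
# dominance, mirroring a cane-yield-like vs quality-trait architecture.
TRAIT_PRESETS = {
    "tch": {"varcomps": (15.82, 3.08, 22.94, 46.10), "het_slope": 92.84},
    "ccs": {"varcomps": (0.19, 0.0, 0.07, 0.21), "het_slope": 0.29},
    "fibre": {"varcomps": (0.85, 0.0, 0.17, 0.68), "het_slope": -0.05},
}


@dataclass
class ExperimentConfig:
    """Scale, trait, and solver parameters of one experiment.

    Defaults are the desk-scale configuration; the full-scale profile
    (2,909 clones, 10,387 markers, 35 parents per sex, 50 progeny per
    cross, 10 iterations) is available via :meth:`full_scale`.
    """

    n_training_clones: int = 400
    n_ancestors: int = 24
    founder_family_size: int = 4
    n_chromosomes: int = 10
    markers_per_chromosome: int = 200
    chromosome_length_morgans: float = 1.5
    maf_min: float = 0.01
    heterozygosity_level: float = 0.2
    n_per_sex: int = 12
    n_progeny_per_cross: int = 20
    n_select: int = 20
    max_per_parent: int = 4
    top_fraction: float = 0.10
    n_iterations: int = 2
    trait: str = "tch"
    trait_varcomps: tuple | None = None
    het_slope: float | None = None
    n_epistatic_pairs: int = 200
    intercept: float = 0.0
    seed: int = 1
    refit_per_iteration: bool = False

    @property
    def n_parents(self) -> int:
        return 2 * self.n_per_sex

    def resolved_trait(self) -> tuple[tuple, float]:
        if self.trait_varcomps is not None:
            slope = self.het_slope if self.het_slope is not None else 0.0
            return tuple(self.trait_varcomps), slope
        preset = TRAIT_PRESETS[self.trait]
        slope = (self.het_slope if self.het_slope is not None
                 else preset["het_slope"])
        return preset["varcomps"], slope

    def validate(self) -> None:
        if self.n_parents > self.n_training_clones:
            raise InvalidParameterError("more parents than training clones")
        if self.n_select > self.n_per_sex * self.max_per_parent:
            raise InvalidParameterError(
                "n_select infeasible under per-parent cap")
        for name in ("n_training_clones", "n_chromosomes",
                     "markers_per_chromosome", "n_per_sex",
                     "n_progeny_per_cross", "n_select", "max_per_parent",
                     "n_iterations"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")

    @classmethod
    def full_scale(cls, **overrides) -> "ExperimentConfig":
        base = dict(n_training_clones=2909, n_chromosomes=10,
                    markers_per_chromosome=1039,
                    chromosome_length_morgans=1.5,
                    n_per_sex=35, n_progeny_per_cross=50, n_select=50,
                    max_per_parent=4, n_iterations=10)
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainingState:
    """Everything fitted once on the training population."""

    gmap: object
    founders: GenotypeMatrix
    arch: TraitArchitecture
    phenotypes: pd.DataFrame
    grms: GRMSet
    het: np.ndarray
    vc_gblup: VarianceComponents
    fit_gblup: MMEFit
    vc_egblup: VarianceComponents
    fit_egblup: MMEFit
    parent_ids: list[str]
    parent_idx: np.ndarray


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    training: TrainingState
    lrt: object
    per_iteration: pd.DataFrame
    aggregate: dict
    n_families: int
    n_progeny_total: int

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"metric": k, "mean": v[0], "sd": v[1]}
                for k, v in self.aggregate.items()]
        return pd.DataFrame(rows)


def generate_training_population(config: ExperimentConfig,
                                 seed_map: int, seed_founders: int,
                                 seed_mating) -> tuple:
    """Training clones as one generation of random mating.

    Elite clonal breeding populations are networks of full- and
    half-sib relatives, and that relatedness is what makes dominance
    and epistatic variance separable from noise.  A small ancestor pool
    is sampled marker-wise, phased, and randomly mated (family size
    ``founder_family_size``); markers falling below the MAF floor in
    the resulting training population are dropped (QC), mirroring the
    marker filtering of real panels.
    """
    gmap = generate_map(config.n_chromosomes, config.markers_per_chromosome,
                        config.chromosome_length_morgans, seed=seed_map)
    ancestors = generate_founders(config.n_ancestors, gmap,
                                  maf_min=config.maf_min,
                                  heterozygosity_level=config.heterozygosity_level,
                                  seed=seed_founders)
    gmap = subset_map(gmap, ancestors.marker_id)
    ss = (seed_mating if isinstance(seed_mating, np.random.SeedSequence)
          else np.random.SeedSequence(seed_mating))
    ss_phase, ss_pairs, ss_meiosis = ss.spawn(3)
    phased = {p.clone_id: p
              for p in phase_genotypes(ancestors, gmap,
                                       np.random.default_rng(ss_phase))}
    rng = np.random.default_rng(ss_pairs)
    ids = list(phased)
    n_crosses = -(-config.n_training_clones // config.founder_family_size)
    crosses = [tuple(rng.choice(ids, 2, replace=False))
               for _ in range(n_crosses)]
    pop, _ = simulate_families(phased, crosses, config.founder_family_size,
                               gmap, ss_meiosis)
    if pop.n_clones > config.n_training_clones:
        pop = pop.subset_clones(np.arange(config.n_training_clones))
    pop = GenotypeMatrix(clone_id=[f"clone{i + 1:04d}"
                                   for i in range(pop.n_clones)],
                         marker_id=pop.marker_id, codes=pop.codes)
    # marker QC on the training population itself
    freqs = allele_frequencies(pop)
    maf = np.minimum(freqs.p, 1.0 - freqs.p)
    keep = maf >= config.maf_min
    if not keep.all():
        logger.info("QC dropped %d markers below MAF %.3f",
                    int((~keep).sum()), config.maf_min)
        pop = GenotypeMatrix(clone_id=pop.clone_id,
                             marker_id=pop.marker_id[keep],
                             codes=pop.codes[:, keep])
        gmap = subset_map(gmap, pop.marker_id)
    return pop, subset_map(gmap, pop.marker_id)


def build_training(config: ExperimentConfig) -> TrainingState:
    """Generate training data, fit both models, select parents by GEBV."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(4)
    s_map, s_found, s_arch, s_phen = [int(c.generate_state(1)[0] % 2**31)
                                      for c in children]
    varcomps, het_slope = config.resolved_trait()

    logger.info("stage data-generation: map + founders")
    founders, gmap = generate_training_population(
        config, s_map, s_found, children[1].spawn(1)[0])
    arch = generate_trait_architecture(
        gmap, varcomps, config.n_epistatic_pairs, het_slope,
        founders, seed=s_arch, intercept=config.intercept)
    phenos = simulate_phenotypes(founders, arch, seed=s_phen)
    y = phenos["phenotype"].to_numpy()

    logger.info("stage model-fitting: GRMs + REML")
    freqs = allele_frequencies(founders)
    grms = GRMSet.from_genotypes(founders, freqs)
    het = genomewide_heterozygosity(founders, freqs)

    vc_g, fit_g = fit_reml(y, None, [grms.g_additive])
    x_ext = np.column_stack([np.ones_like(y), het - het.mean()])
    vc_e, fit_e = fit_reml(y, x_ext, [grms.g_additive, grms.g_dominance,
                                      grms.g_epistatic])
    fit_e.het_center = float(het.mean())

    order = np.argsort(fit_g.u_hat)[::-1]
    parent_idx = order[:config.n_parents]
    parent_ids = [founders.clone_id[i] for i in parent_idx]
    return TrainingState(gmap=gmap, founders=founders, arch=arch,
                         phenotypes=phenos, grms=grms, het=het,
                         vc_gblup=vc_g, fit_gblup=fit_g,
                         vc_egblup=vc_e, fit_egblup=fit_e,
                         parent_ids=parent_ids, parent_idx=parent_idx)


def run_iteration(state: TrainingState, config: ExperimentConfig,
                  iteration: int,
                  iter_seed: np.random.SeedSequence) -> dict:
    """One sex split + factorial simulation + both ILPs."""
    t0 = time.perf_counter()
    ss_split, ss_phase, ss_meiosis = iter_seed.spawn(3)
    rng_split = np.random.default_rng(ss_split)
    perm = rng_split.permutation(config.n_parents)
    females = [state.parent_ids[i] for i in perm[:config.n_per_sex]]
    males = [state.parent_ids[i] for i in perm[config.n_per_sex:]]

    parents_gm = state.founders.subset_clones(
        [state.founders.clone_id.index(pid)
         for pid in females + males])
    phased = {p.clone_id: p
              for p in phase_genotypes(parents_gm, state.gmap,
                                       np.random.default_rng(ss_phase))}
    crosses = enumerate_crosses(females, males)
    progeny, family = simulate_families(phased, crosses,
                                        config.n_progeny_per_cross,
                                        state.gmap, ss_meiosis)

    blocks = cross_block_grms(state.founders, progeny,
                              train_grms=state.grms)
    pred_u = predict_progeny(state.fit_gblup, blocks,
                             progeny_ids=progeny.clone_id)
    pred_g = predict_progeny(state.fit_egblup, blocks,
                             progeny_ids=progeny.clone_id)
    preds = pd.DataFrame({
        "clone_id": progeny.clone_id,
        "u_hat": pred_u["u_hat"].to_numpy(),
        "g_hat": pred_g["g_hat"].to_numpy(),
    })
    progeny_f = blocks.progeny_diag_a - 1.0

    merit = cross_merit(preds, family, progeny_f=progeny_f,
                        top_fraction=config.top_fraction)
    plan_gebv = select_crosses_ilp(merit, objective="u_cross",
                                   n_select=config.n_select,
                                   max_per_parent=config.max_per_parent)
    plan_gpcp = select_crosses_ilp(merit, objective="g_cross",
                                   n_select=config.n_select,
                                   max_per_parent=config.max_per_parent)
    row = strategy_comparison(merit, plan_gebv, plan_gpcp)
    row["plans_valid"] = bool(
        validate_plan(plan_gebv, merit, config.n_select,
                      config.max_per_parent)
        and validate_plan(plan_gpcp, merit, config.n_select,
                          config.max_per_parent))

    # realized (true) clonal value of the selected families, known in
    # simulation: family-mean true total genetic value
    truth = genetic_value(progeny, state.arch)
    fam_truth = (pd.DataFrame({
        "female_id": family["female_id"],
        "male_id": family["male_id"],
        "total": truth["total"].to_numpy(),
    }).groupby(["female_id", "male_id"], sort=False)["total"].mean())
    key = merit.set_index(["female_id", "male_id"]).index
    fam_truth = fam_truth.reindex(key).to_numpy()
    row["true_g_gebv"] = float(fam_truth[plan_gebv.selected].mean())
    row["true_g_gpcp"] = float(fam_truth[plan_gpcp.selected].mean())
    row["iteration"] = iteration
    row["n_families"] = len(merit)
    row["n_progeny"] = progeny.n_clones
    row["runtime_s"] = time.perf_counter() - t0
    return row


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Full experiment: training fits once, then seeded iterations."""
    state = build_training(config)
    lrt = likelihood_ratio_test(state.vc_egblup.log_likelihood,
                                state.vc_gblup.log_likelihood)
    iter_seeds = np.random.SeedSequence(config.seed).spawn(4 + config.n_iterations)[4:]
    rows = []
    for i, ss in enumerate(iter_seeds, start=1):
        if config.refit_per_iteration and i > 1:
            state = build_training(config)
        logger.info("stage iteration %d/%d", i, config.n_iterations)
        rows.append(run_iteration(state, config, i, ss))
    per_iter = pd.DataFrame(rows)
    metrics = [c for c in per_iter.columns
               if c not in ("iteration", "n_families", "n_progeny",
                            "runtime_s")]
    aggregate = {m: (float(per_iter[m].mean()),
                     float(per_iter[m].std(ddof=1))
                     if len(per_iter) > 1 else 0.0)
                 for m in metrics}
    return ExperimentReport(
        config=config, training=state, lrt=lrt,
        per_iteration=per_iter, aggregate=aggregate,
        n_families=int(per_iter["n_families"].iloc[0]),
        n_progeny_total=int(per_iter["n_progeny"].sum()),
    )
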