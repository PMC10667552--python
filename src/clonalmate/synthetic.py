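"""Synthetic founder populations, genetic maps, and trait architectures.

The real breeding data this analysis is designed for (elite clonal hybrids
phenotyped in late-stage trials) is confidential, so everything downstream
is exercised on generated data with the same statistical structure:
biallelic markers with a minor-allele-frequency floor on a Morgan-scale
multi-chromosome map, clones more heterozygous than Hardy-Weinberg
equilibrium would give (as clonal hybrids are), and traits whose genetic
variance decomposes into additive, dominance, additive-additive epistatic,
and genome-wide-heterozygosity components of configurable size.

Trait truth is carried by a finite set of marker effects (plus a finite
set of epistatic marker pairs) so that genetic values are heritable
through simulated meiosis.  A separate multivariate-normal generator
(:func:`mvn_phenotypes`) draws phenotypes from the *exact* relationship-
matrix model and exists for variance-component recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .containers import (
    AlleleFrequencies,
    DegenerateInputError,
    DimensionError,
    GeneticMap,
    GenotypeMatrix,
    InvalidParameterError,
)
from .relationships import dominance_covariates, genomewide_heterozygosity

DEFAULT_HET_LEVEL = 0.2   # 1.2x HWE heterozygosity, typical of clonal hybrids


def generate_map(n_chromosomes: int, markers_per_chromosome: int,
                 chromosome_length_morgans: float, seed: int) -> GeneticMap:
    """Uniform random marker positions on equal-length chromosomes."""
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise InvalidParameterError("counts must be >= 1")
    if chromosome_length_morgans <= 0:
        raise InvalidParameterError("chromosome length must be positive")
    rng = np.random.default_rng(seed)
    chroms, positions, names = [], [], []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(rng.uniform(0.0, chromosome_length_morgans,
                                  markers_per_chromosome))
        # ties are measure-zero but would break strict monotonicity
        while len(np.unique(pos)) < markers_per_chromosome:
            pos = np.sort(rng.uniform(0.0, chromosome_length_morgans,
                                      markers_per_chromosome))
        chroms.append(np.full(markers_per_chromosome, c))
        positions.append(pos)
        names.extend(f"chr{c}_m{i + 1}" for i in range(markers_per_chromosome))
    return GeneticMap(
        marker_id=np.array(names),
        chromosome=np.concatenate(chroms),
        position=np.concatenate(positions),
        chromosome_length={c: chromosome_length_morgans
                           for c in range(1, n_chromosomes + 1)},
    )


def _genotype_probs(p: np.ndarray, het_level: float) -> np.ndarray:
    """Genotype frequencies with heterozygosity inflated (1+het_level)x
    over HWE, capped at feasibility (h <= 2 min(p, q))."""
    q = 1.0 - p
    h = np.minimum((1.0 + het_level) * 2.0 * p * q,
                   2.0 * np.minimum(p, q))
    return np.stack([q - h / 2.0, h, p - h / 2.0], axis=-1)  # P(0), P(1), P(2)


def generate_founders(n_clones: int, gmap: GeneticMap,
                      maf_min: float = 0.01,
                      heterozygosity_level: float = DEFAULT_HET_LEVEL,
                      seed: int = 0,
                      max_resample: int = 20) -> GenotypeMatrix:
    """Sample a founder population marker-by-marker.

    Major-allele frequencies are drawn Uniform(0.5, 1 - maf_min) per
    marker, genotypes sampled from heterozygosity-inflated genotype
    frequencies, and any marker whose *sample* MAF falls below
    ``maf_min`` is resampled (new frequency and genotypes); markers
    still failing after ``max_resample`` tries are dropped.
    """
    if n_clones < 2:
        raise InvalidParameterError("need at least 2 clones")
    if not 0.0 < maf_min < 0.5:
        raise InvalidParameterError("maf_min must be in (0, 0.5)")
    if not 0.0 <= heterozygosity_level <= 1.0:
        raise InvalidParameterError("heterozygosity_level must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    codes = np.empty((n_clones, m), dtype=np.int8)
    keep = np.ones(m, dtype=bool)
    for j in range(m):
        ok = False
        for _ in range(max_resample):
            p = rng.uniform(0.5, 1.0 - maf_min)
            col = rng.choice(np.array([0, 1, 2], dtype=np.int8),
                             size=n_clones,
                             p=_genotype_probs(np.array(p),
                                               heterozygosity_level))
            freq = col.mean() / 2.0
            if maf_min <= min(freq, 1.0 - freq):
                ok = True
                break
        codes[:, j] = col
        keep[j] = ok
    if not keep.all():
        codes = codes[:, keep]
    return GenotypeMatrix(
        clone_id=[f"clone{i + 1:04d}" for i in range(n_clones)],
        marker_id=gmap.marker_id[keep],
        codes=codes,
    )


def subset_map(gmap: GeneticMap, marker_ids: np.ndarray) -> GeneticMap:
    """Restrict a map to the markers a genotype matrix retained."""
    keep = np.isin(gmap.marker_id, marker_ids)
    return GeneticMap(marker_id=gmap.marker_id[keep],
                      chromosome=gmap.chromosome[keep],
                      position=gmap.position[keep],
                      chromosome_length=gmap.chromosome_length)


@dataclass
class TraitArchitecture:
    """True marker-level genetic architecture of one trait.

    Effects are stored after rescaling so that each component's variance
    over the founder population matches its target; the heterozygosity
    slope ``het_slope`` is stored unscaled (it is a fixed regression, not
    a variance component).  ``freqs`` are the founder allele frequencies
    the covariates are centered on.
    """

    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    epistatic_pairs: list[tuple[int, int, float]]
    het_slope: float
    residual_sd: float
    target_varcomps: tuple[float, float, float, float]  # (A, D, AA, eps)
    freqs: AlleleFrequencies
    intercept: float = 0.0
    marker_id: np.ndarray = field(default=None)


def _component_values(codes: np.ndarray, arch: TraitArchitecture):
    p = arch.freqs.p
    wc = codes.astype(float) - 2.0 * p
    u = wc @ arch.additive_effects
    gm = GenotypeMatrix(clone_id=[str(i) for i in range(codes.shape[0])],
                        marker_id=arch.marker_id, codes=codes)
    hd = dominance_covariates(gm, arch.freqs) * (2.0 * p * (1.0 - p))
    # hd is the centered dominance covariate x_D - 2p^2
    d = hd @ arch.dominance_effects
    t = np.zeros(codes.shape[0])
    for i, j, e in arch.epistatic_pairs:
        t += e * wc[:, i] * wc[:, j]
    het = genomewide_heterozygosity(gm, arch.freqs)
    return u, d, t, het


def generate_trait_architecture(gmap: GeneticMap,
                                target_varcomps: tuple[float, float, float, float],
                                n_epistatic_pairs: int,
                                het_slope: float,
                                founders: GenotypeMatrix,
                                seed: int = 0,
                                intercept: float = 0.0) -> TraitArchitecture:
    """Sample marker effects and rescale them to the target variances.

    ``target_varcomps`` = (sigma2_A, sigma2_D, sigma2_AA, sigma2_eps) on
    the trait scale.  Effects are N(0,1) draws rescaled so the realized
    variance of each genetic component over ``founders`` equals its
    target (a zero target zeroes the component).
    """
    if any(v < 0 for v in target_varcomps):
        raise InvalidParameterError("target variances must be >= 0")
    m = founders.n_markers
    if n_epistatic_pairs > m * (m - 1) // 2:
        raise InvalidParameterError("more epistatic pairs than marker pairs")
    rng = np.random.default_rng(seed)
    from .relationships import allele_frequencies
    freqs = allele_frequencies(founders, source="founders")

    s2a, s2d, s2aa, s2e = target_varcomps
    add = rng.normal(size=m)
    dom = rng.normal(size=m) if s2d > 0 else np.zeros(m)
    pairs: list[tuple[int, int, float]] = []
    if n_epistatic_pairs > 0 and s2aa > 0:
        seen = set()
        while len(pairs) < n_epistatic_pairs:
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            pairs.append((int(key[0]), int(key[1]), float(rng.normal())))

    arch = TraitArchitecture(additive_effects=add, dominance_effects=dom,
                             epistatic_pairs=pairs, het_slope=het_slope,
                             residual_sd=float(np.sqrt(s2e)),
                             target_varcomps=tuple(target_varcomps),
                             freqs=freqs, intercept=intercept,
                             marker_id=founders.marker_id)
    u, d, t, _ = _component_values(founders.codes, arch)
    for vec, target, attr in ((u, s2a, "additive_effects"),
                              (d, s2d, "dominance_effects")):
        var = vec.var()
        if target > 0:
            if var <= 0:
                raise DegenerateInputError(
                    f"{attr} realized variance is zero; cannot scale")
            setattr(arch, attr, getattr(arch, attr) * np.sqrt(target / var))
        else:
            setattr(arch, attr, np.zeros(m))
    if pairs:
        var = t.var()
        if s2aa > 0:
            scale = np.sqrt(s2aa / var)
            arch.epistatic_pairs = [(i, j, e * scale) for i, j, e in pairs]
        else:
            arch.epistatic_pairs = []
    return arch


def genetic_value(genotypes: GenotypeMatrix,
                  arch: TraitArchitecture) -> pd.DataFrame:
    """True genetic components per clone: u, d, t, het term, and total."""
    if genotypes.n_markers != len(arch.additive_effects):
        raise DimensionError("genotypes do not conform to architecture")
    u, d, t, het = _component_values(genotypes.codes, arch)
    het_term = arch.het_slope * het
    return pd.DataFrame({
        "clone_id": genotypes.clone_id,
        "u_true": u, "d_true": d, "t_true": t,
        "het_term": het_term,
        "total": u + d + t + het_term,
    })


def simulate_phenotypes(genotypes: GenotypeMatrix, arch: TraitArchitecture,
                        seed: int = 0) -> pd.DataFrame:
    """One adjusted phenotypic record per clone: intercept + genetic
    total + N(0, residual_sd^2) noise."""
    if arch.residual_sd < 0:
        raise InvalidParameterError("residual_sd must be >= 0")
    rng = np.random.default_rng(seed)
    vals = genetic_value(genotypes, arch)
    noise = rng.normal(0.0, arch.residual_sd, size=genotypes.n_clones)
    return pd.DataFrame({
        "clone_id": genotypes.clone_id,
        "phenotype": arch.intercept + vals["total"].to_numpy() + noise,
    })


def mvn_phenotypes(grms: list[np.ndarray],
                   varcomps: tuple,
                   het_vector: np.ndarray | None = None,
                   het_slope: float = 0.0,
                   seed: int = 0,
                   mu: float = 0.0,
                   jitter: float = 1e-8,
                   psd_clip: bool = True) -> np.ndarray:
    """Draw phenotypes from the exact relationship-matrix model.

    y = mu + sum_i g_i + b * Het + eps with g_i ~ N(0, sigma2_i G_i) and
    eps ~ N(0, sigma2_eps I).  ``varcomps`` holds one variance per GRM
    followed by the residual variance.  Used to verify that REML recovers
    known components when the model is exactly true.

    The unbiased-diagonal additive GRM of an excess-heterozygosity
    population is mildly indefinite; with ``psd_clip`` the matrix root
    is taken after projecting onto the nearest PSD matrix (negative
    eigenvalues clipped to zero).  With ``psd_clip=False`` any matrix
    that is not PSD beyond the jitter raises a decomposition error.
    """
    if len(varcomps) != len(grms) + 1:
        raise DimensionError("need one variance per GRM plus a residual")
    if any(v < 0 for v in varcomps):
        raise InvalidParameterError("variances must be >= 0")
    n = len(grms[0]) if grms else len(het_vector)
    rng = np.random.default_rng(seed)
    y = np.full(n, mu)
    for g, s2 in zip(grms, varcomps[:-1]):
        if s2 == 0.0:
            continue
        try:
            root = cholesky(s2 * (g + jitter * np.eye(n)), lower=True)
        except np.linalg.LinAlgError as err:
            if not psd_clip:
                raise DegenerateInputError(
                    "GRM not positive semi-definite beyond jitter") from err
            vals, vecs = np.linalg.eigh(g)
            root = vecs * np.sqrt(s2 * np.clip(vals, 0.0, None))
        y += root @ rng.normal(size=n)
    if het_vector is not None and het_slope != 0.0:
        y += het_slope * np.asarray(het_vector)
    if varcomps[-1] > 0.0:
        y += rng.normal(0.0, np.sqrt(varcomps[-1]), size=n)
    return y
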