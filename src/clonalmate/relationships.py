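"""Genomic relationship matrices, heterozygosity, and inbreeding.

All statistics are defined relative to a fixed set of allele frequencies
(by default those of the training population), so that simulated progeny
are measured against the same base population as their parents.

Additive matrix
    G_A[j,k] = (1/n) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i q_i)  (j != k)
    G_A[j,j] = 1 + (1/n) sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i q_i)
with x the 0/1/2 major-allele dosage.  The diagonal uses the unbiased
self-relationship form, whose mean is 1 + mean inbreeding.

Dominance matrix
    G_D = H H' / n with h_ij = (x_D,ij - 2 p_i^2) / (2 p_i q_i) and the
    dominance covariate x_D in {0, 2p, 4p - 2} for minor homozygote,
    heterozygote, major homozygote.  At Hardy-Weinberg genotype
    frequencies this coding is orthogonal to the additive one.

Additive-additive epistasis
    G_AA = (G_A . G_A) / (tr(G_A . G_A) / m), the Hadamard square of G_A
    scaled so its mean diagonal is exactly one.

Genome-wide heterozygosity
    Het_k = (number of heterozygous loci of clone k) / sum_i 2 p_i q_i,
    the observed/expected heterozygosity ratio (~1 for an HWE clone).

Genomic inbreeding
    F_k = G_A[k,k] - 1; negative values mean the clone is more
    heterozygous than the base population average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    MISSING,
    AlleleFrequencies,
    DegenerateInputError,
    DimensionError,
    GenotypeMatrix,
)

logger = logging.getLogger(__name__)


def allele_frequencies(genotypes: GenotypeMatrix,
                       source: str = "training") -> AlleleFrequencies:
    """Per-marker major-allele frequency p = mean dosage / 2.

    Missing codes are excluded marker-wise (pairwise-complete counting).
    Markers that come out monomorphic (p in {0,1}) or all-missing are
    flagged via :attr:`AlleleFrequencies.monomorphic` and logged; they
    must be removed before any matrix construction.
    """
    codes = genotypes.codes.astype(float)
    obs = genotypes.codes != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0,
                     np.where(obs, codes, 0.0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1)),
                     1.0)
    all_missing = n_obs == 0
    if all_missing.any():
        logger.warning("%d markers all-missing; flagged monomorphic",
                       int(all_missing.sum()))
    freqs = AlleleFrequencies(p=p, source=source)
    n_mono = int(freqs.monomorphic.sum())
    if n_mono:
        logger.info("%d monomorphic markers flagged for exclusion", n_mono)
    return freqs


def _check_polymorphic(freqs: AlleleFrequencies) -> None:
    if freqs.monomorphic.any():
        raise DegenerateInputError(
            f"{int(freqs.monomorphic.sum())} monomorphic markers present; "
            "filter them before building relationship matrices")


def _imputed_dosages(genotypes: GenotypeMatrix,
                     freqs: AlleleFrequencies) -> np.ndarray:
    """Float dosages with missing codes mean-imputed as 2p (logged)."""
    x = genotypes.codes.astype(float)
    miss = genotypes.codes == MISSING
    if miss.any():
        logger.info("mean-imputing %d missing genotypes with 2p",
                    int(miss.sum()))
        x[miss] = np.broadcast_to(2.0 * freqs.p, x.shape)[miss]
    return x


def _additive_diag(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    den = 2.0 * p * (1.0 - p)
    return 1.0 + ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / den).mean(axis=1)


def additive_grm(genotypes: GenotypeMatrix,
                 freqs: AlleleFrequencies) -> np.ndarray:
    """Additive GRM with per-marker standardisation (GCTA-style elements)."""
    _check_polymorphic(freqs)
    if genotypes.n_markers != freqs.n_markers:
        raise DimensionError("genotypes and frequencies marker counts differ")
    x = _imputed_dosages(genotypes, freqs)
    p = freqs.p
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    g = (w @ w.T) / genotypes.n_markers
    np.fill_diagonal(g, _additive_diag(x, p))
    return g


def dominance_covariates(genotypes: GenotypeMatrix,
                         freqs: AlleleFrequencies) -> np.ndarray:
    """Standardised dominance incidence matrix H (clones x markers)."""
    _check_polymorphic(freqs)
    x = _imputed_dosages(genotypes, freqs)
    p = freqs.p
    # x_D: 0 -> 0, 1 -> 2p, 2 -> 4p-2 (orthogonal-to-additive coding)
    xd = np.select([x == 0.0, x == 1.0, x == 2.0],
                   [np.zeros_like(x),
                    np.broadcast_to(2.0 * p, x.shape),
                    np.broadcast_to(4.0 * p - 2.0, x.shape)],
                   default=np.nan)
    if np.isnan(xd).any():
        # imputed (fractional) dosages: linear interpolation of the coding
        frac = np.isnan(xd)
        xi = x[frac]
        pi = np.broadcast_to(p, x.shape)[frac]
        lo = np.where(xi < 1.0, 0.0, 2.0 * pi)
        hi = np.where(xi < 1.0, 2.0 * pi, 4.0 * pi - 2.0)
        t = np.where(xi < 1.0, xi, xi - 1.0)
        xd[frac] = lo + t * (hi - lo)
    return (xd - 2.0 * p * p) / (2.0 * p * (1.0 - p))


def dominance_grm(genotypes: GenotypeMatrix,
                  freqs: AlleleFrequencies) -> np.ndarray:
    """Dominance GRM G_D = H H' / n."""
    h = dominance_covariates(genotypes, freqs)
    return (h @ h.T) / genotypes.n_markers


def epistatic_grm(g_additive: np.ndarray) -> np.ndarray:
    """Additive-additive GRM: normalised Hadamard square of G_A."""
    g = np.asarray(g_additive, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise DimensionError("G_A must be square")
    had = g * g
    norm = np.trace(had) / g.shape[0]
    if norm <= 0.0:
        raise DegenerateInputError("trace of Hadamard square is zero")
    return had / norm


def epistatic_normalizer(g_additive: np.ndarray) -> float:
    """tr(G_A . G_A)/m — frozen from training for progeny blocks."""
    norm = float(np.mean(np.diag(g_additive) ** 2))
    if norm <= 0.0:
        raise DegenerateInputError("trace of Hadamard square is zero")
    return norm


def genomewide_heterozygosity(genotypes: GenotypeMatrix,
                              freqs: AlleleFrequencies,
                              numerator: str = "indicator") -> np.ndarray:
    """Observed/expected heterozygosity ratio Het_k per clone.

    ``numerator='indicator'`` (default) counts heterozygous loci;
    ``numerator='h_element'`` instead sums the elements of the dominance
    incidence matrix H — an alternative literal reading of the same
    statistic, kept behind this flag.
    """
    _check_polymorphic(freqs)
    denom = float(np.sum(2.0 * freqs.p * freqs.q))
    if denom <= 0.0:
        raise DegenerateInputError("expected heterozygosity sums to zero")
    if numerator == "indicator":
        num = (genotypes.codes == 1).sum(axis=1).astype(float)
    elif numerator == "h_element":
        num = dominance_covariates(genotypes, freqs).sum(axis=1)
    else:
        raise ValueError(f"unknown numerator mode {numerator!r}")
    return num / denom


def inbreeding_coefficients(genotypes: GenotypeMatrix,
                            freqs: AlleleFrequencies) -> np.ndarray:
    """Genomic inbreeding F_k = G_A[k,k] - 1 (may be negative)."""
    _check_polymorphic(freqs)
    x = _imputed_dosages(genotypes, freqs)
    return _additive_diag(x, freqs.p) - 1.0


@dataclass
class GRMSet:
    """The three relationship matrices of one training population."""

    g_additive: np.ndarray
    g_dominance: np.ndarray
    g_epistatic: np.ndarray
    frequencies: AlleleFrequencies
    n_markers: int
    gaa_normalizer: float = field(default=np.nan)

    @classmethod
    def from_genotypes(cls, genotypes: GenotypeMatrix,
                       freqs: AlleleFrequencies | None = None) -> "GRMSet":
        if freqs is None:
            freqs = allele_frequencies(genotypes)
        ga = additive_grm(genotypes, freqs)
        gd = dominance_grm(genotypes, freqs)
        gaa = epistatic_grm(ga)
        return cls(g_additive=ga, g_dominance=gd, g_epistatic=gaa,
                   frequencies=freqs, n_markers=genotypes.n_markers,
                   gaa_normalizer=epistatic_normalizer(ga))


@dataclass
class CrossBlockGRMs:
    """Progeny x training relationship blocks, on training frequencies.

    ``a_block``/``d_block``/``aa_block`` are (n_progeny x n_train); the
    epistatic block is the Hadamard square of the additive block divided
    by the *training* normaliser, so progeny are measured on the training
    scale.  ``progeny_diag_a`` is the additive self-relationship of each
    progeny (1 + F).
    """

    a_block: np.ndarray
    d_block: np.ndarray
    aa_block: np.ndarray
    progeny_diag_a: np.ndarray
    progeny_het: np.ndarray
    train: GRMSet


def cross_block_grms(train_genotypes: GenotypeMatrix,
                     progeny_genotypes: GenotypeMatrix,
                     freqs: AlleleFrequencies | None = None,
                     train_grms: GRMSet | None = None,
                     block_size: int = 2048) -> CrossBlockGRMs:
    """Relationship blocks between progeny and the training set.

    Computed in progeny blocks of ``block_size`` so memory stays bounded
    at paper scale (tens of thousands of progeny).
    """
    if train_grms is None:
        train_grms = GRMSet.from_genotypes(train_genotypes, freqs)
    freqs = train_grms.frequencies
    if progeny_genotypes.n_markers != train_genotypes.n_markers:
        raise DimensionError("progeny and training marker sets differ")
    _check_polymorphic(freqs)
    p = freqs.p
    n_mark = train_genotypes.n_markers
    scale = np.sqrt(2.0 * p * (1.0 - p))
    w_train = (_imputed_dosages(train_genotypes, freqs) - 2.0 * p) / scale
    h_train = dominance_covariates(train_genotypes, freqs)

    n_prog = progeny_genotypes.n_clones
    n_train = train_genotypes.n_clones
    a_block = np.empty((n_prog, n_train))
    d_block = np.empty((n_prog, n_train))
    diag_a = np.empty(n_prog)
    for start in range(0, n_prog, block_size):
        stop = min(start + block_size, n_prog)
        chunk = progeny_genotypes.subset_clones(np.arange(start, stop))
        x = _imputed_dosages(chunk, freqs)
        w = (x - 2.0 * p) / scale
        a_block[start:stop] = (w @ w_train.T) / n_mark
        d_block[start:stop] = (dominance_covariates(chunk, freqs)
                               @ h_train.T) / n_mark
        diag_a[start:stop] = _additive_diag(x, p)
    aa_block = (a_block * a_block) / train_grms.gaa_normalizer
    het = genomewide_heterozygosity(progeny_genotypes, freqs)
    return CrossBlockGRMs(a_block=a_block, d_block=d_block,
                          aa_block=aa_block, progeny_diag_a=diag_a,
                          progeny_het=het, train=train_grms)
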