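"""Gamete and progeny simulation under the count-location crossover model.

Meiosis is strictly diploid and interference-free: per chromosome the
crossover count is Poisson with mean equal to the chromosome's genetic
length in Morgans, and crossover locations are i.i.d. uniform along the
chromosome.  These assumptions imply the Haldane mapping function
r = (1 - exp(-2 d)) / 2 between loci d Morgans apart.

Two samplers are provided:

* :func:`sample_gamete` — the literal positional algorithm (draw the
  Poisson count, place the crossovers, read off the source haplotype at
  each marker).  One gamete per call; can also report the realized
  crossover counts.
* :func:`sample_gametes` — a vectorised marker-interval algorithm:
  between adjacent markers d apart the gamete switches source haplotype
  with probability (1 - exp(-2 d)) / 2, independently across intervals.
  Because a Poisson process drops an odd number of points in an interval
  of length d with exactly that probability, and counts in disjoint
  intervals are independent, the two samplers are distributionally
  identical at the markers.  Crossovers falling between markers that
  flank no marker have no observable effect either way.

Phase is not observed in dosage data, so heterozygous loci are phased
uniformly at random, once per parent per run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    DimensionError,
    GeneticMap,
    GenotypeMatrix,
    InvalidParameterError,
)


@dataclass
class PhasedParent:
    """Two haplotypes (alleles in {0,1}; 1 = major) aligned to a map."""

    clone_id: str
    haplotypes: np.ndarray       # (2, n_markers) int8

    def __post_init__(self) -> None:
        if self.haplotypes.shape[0] != 2:
            raise DimensionError("a diploid parent has exactly 2 haplotypes")

    @property
    def dosage(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0)


def phase_genotypes(genotypes: GenotypeMatrix, gmap: GeneticMap,
                    rng: np.random.Generator) -> list[PhasedParent]:
    """Impose gametic phase on dosage genotypes.

    Homozygotes phase deterministically; each heterozygous locus gets an
    independent uniform random phase, fixed for the run.  Missing codes
    are an error — impute upstream.
    """
    if genotypes.n_markers != gmap.n_markers:
        raise DimensionError("genotypes and map marker counts differ")
    if genotypes.has_missing:
        raise InvalidParameterError(
            "cannot phase missing genotypes; impute first")
    codes = genotypes.codes
    coin = rng.integers(0, 2, size=codes.shape).astype(np.int8)
    hap0 = np.where(codes == 2, 1, np.where(codes == 1, coin, 0)).astype(np.int8)
    hap1 = (codes - hap0).astype(np.int8)
    return [PhasedParent(clone_id=cid, haplotypes=np.stack([hap0[i], hap1[i]]))
            for i, cid in enumerate(genotypes.clone_id)]


def _chrom_lengths(gmap: GeneticMap) -> dict[int, float]:
    out = {}
    for c in gmap.chromosomes:
        idx = gmap.chrom_slice(c)
        out[int(c)] = gmap.chromosome_length.get(
            int(c), float(gmap.position[idx][-1]))
    return out


def sample_gamete(parent: PhasedParent, gmap: GeneticMap,
                  rng: np.random.Generator,
                  return_counts: bool = False):
    """One gamete by the positional count-location algorithm.

    Per chromosome: k ~ Poisson(L), k crossover locations i.i.d.
    Uniform(0, L), starting haplotype fair-coin; the source haplotype at
    a marker is start XOR (number of crossovers left of it).
    """
    lengths = _chrom_lengths(gmap)
    gamete = np.empty(gmap.n_markers, dtype=np.int8)
    counts = {}
    for c in gmap.chromosomes:
        idx = gmap.chrom_slice(c)
        pos = gmap.position[idx]
        length = lengths[int(c)]
        k = rng.poisson(length)
        locs = np.sort(rng.uniform(0.0, length, size=k))
        start = rng.integers(0, 2)
        source = (start + np.searchsorted(locs, pos)) % 2
        gamete[idx] = parent.haplotypes[source, idx]
        counts[int(c)] = int(k)
    if return_counts:
        return gamete, counts
    return gamete


def _interval_switch_probs(gmap: GeneticMap) -> dict[int, np.ndarray]:
    """Haldane switch probability per adjacent-marker interval."""
    probs = {}
    for c in gmap.chromosomes:
        d = np.diff(gmap.position[gmap.chrom_slice(c)])
        probs[int(c)] = 0.5 * (1.0 - np.exp(-2.0 * d))
    return probs


def sample_gametes(parent: PhasedParent, gmap: GeneticMap,
                   rng: np.random.Generator, n: int) -> np.ndarray:
    """n gametes at once by the marker-interval algorithm (see module
    docstring for the distributional-identity argument)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    gametes = np.empty((n, gmap.n_markers), dtype=np.int8)
    switch = _interval_switch_probs(gmap)
    for c in gmap.chromosomes:
        idx = gmap.chrom_slice(c)
        m = len(idx)
        start = rng.integers(0, 2, size=n, dtype=np.int64)
        if m > 1:
            flips = (rng.random((n, m - 1)) < switch[int(c)]).astype(np.int64)
            source = np.empty((n, m), dtype=np.int64)
            source[:, 0] = start
            source[:, 1:] = (start[:, None] + np.cumsum(flips, axis=1)) % 2
        else:
            source = start[:, None]
        hap = parent.haplotypes[:, idx]
        gametes[:, idx] = hap[source, np.arange(m)]
    return gametes


def make_cross(female: PhasedParent, male: PhasedParent, n_progeny: int,
               gmap: GeneticMap, rng: np.random.Generator,
               family_prefix: str | None = None) -> GenotypeMatrix:
    """Progeny dosage genotypes of one cross: one gamete from each
    parent per progeny, re-encoded to {0,1,2}."""
    if n_progeny < 1:
        raise InvalidParameterError("n_progeny must be >= 1")
    g_f = sample_gametes(female, gmap, rng, n_progeny)
    g_m = sample_gametes(male, gmap, rng, n_progeny)
    codes = (g_f + g_m).astype(np.int8)
    prefix = family_prefix or f"{female.clone_id}x{male.clone_id}"
    ids = [f"{prefix}_p{k + 1}" for k in range(n_progeny)]
    return GenotypeMatrix(clone_id=ids, marker_id=gmap.marker_id, codes=codes)


def simulate_families(parents: dict[str, PhasedParent],
                      cross_list: list[tuple[str, str]],
                      n_progeny: int, gmap: GeneticMap,
                      seed) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """All requested crosses, each from its own deterministic substream.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`; each
    cross gets a child stream keyed by its position in ``cross_list``,
    so families reproduce independently of execution order.
    """
    for f, m in cross_list:
        for pid in (f, m):
            if pid not in parents:
                raise KeyError(f"unknown parent id {pid!r}")
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    children = root.spawn(len(cross_list))
    blocks, fam_rows = [], []
    for (f, m), ss in zip(cross_list, children):
        rng = np.random.default_rng(ss)
        fam = make_cross(parents[f], parents[m], n_progeny, gmap, rng)
        blocks.append(fam.codes)
        fam_rows.extend((pid, f, m) for pid in fam.clone_id)
    if not blocks:
        empty = GenotypeMatrix(clone_id=[], marker_id=gmap.marker_id,
                               codes=np.empty((0, gmap.n_markers), np.int8))
        return empty, pd.DataFrame(columns=["progeny_id", "female_id",
                                            "male_id"])
    progeny = GenotypeMatrix(
        clone_id=[r[0] for r in fam_rows],
        marker_id=gmap.marker_id,
        codes=np.concatenate(blocks, axis=0),
    )
    family = pd.DataFrame(fam_rows,
                          columns=["progeny_id", "female_id", "male_id"])
    return progeny, family
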