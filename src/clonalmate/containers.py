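"""Core in-memory containers shared across the package.

Genotypes are pseudo-diploid dosages of the major allele: 2 = homozygous
major, 1 = heterozygous, 0 = homozygous minor, -1 = missing.  Map positions
are in Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


class InvalidParameterError(ValueError):
    """A caller-supplied parameter is outside its documented domain."""


class DimensionError(ValueError):
    """Inputs whose shapes/marker sets do not agree."""


class DegenerateInputError(ValueError):
    """Structurally valid input on which the operation is undefined
    (zero variance, zero denominator, zero trace...)."""


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions (Morgans) on numbered chromosomes.

    Positions are strictly increasing within a chromosome and bounded by
    the chromosome length; marker ids are unique.
    """

    marker_id: np.ndarray        # (m,) str
    chromosome: np.ndarray       # (m,) int, >= 1
    position: np.ndarray         # (m,) float, Morgans
    chromosome_length: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.marker_id)
        if not (len(self.chromosome) == len(self.position) == m):
            raise DimensionError("map columns have unequal lengths")
        if len(np.unique(self.marker_id)) != m:
            raise InvalidParameterError("marker ids are not unique")
        for c in np.unique(self.chromosome):
            pos = self.position[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise InvalidParameterError(
                    f"positions not strictly increasing on chromosome {c}")
            length = self.chromosome_length.get(int(c))
            if length is not None and pos[-1] > length + 1e-12:
                raise InvalidParameterError(
                    f"position beyond chromosome {c} length")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_slice(self, c: int) -> np.ndarray:
        """Indices of markers on chromosome ``c`` (map order)."""
        return np.flatnonzero(self.chromosome == c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker_id": self.marker_id,
            "chromosome": self.chromosome,
            "position_morgan": self.position,
        })


@dataclass
class GenotypeMatrix:
    """Clones x markers dosage codes in {0, 1, 2}, -1 for missing."""

    clone_id: list[str]
    marker_id: np.ndarray
    codes: np.ndarray            # (n_clones, m) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise DimensionError("codes must be 2-D (clones x markers)")
        if self.codes.shape != (len(self.clone_id), len(self.marker_id)):
            raise DimensionError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.clone_id)} clones x {len(self.marker_id)} markers")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise InvalidParameterError(
                f"{bad.sum()} genotype codes outside {{0,1,2,-1}}")

    @property
    def n_clones(self) -> int:
        return len(self.clone_id)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def has_missing(self) -> bool:
        return bool((self.codes == MISSING).any())

    def subset_clones(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            clone_id=[self.clone_id[i] for i in idx],
            marker_id=self.marker_id,
            codes=self.codes[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.marker_id)
        df.insert(0, "clone_id", self.clone_id)
        return df


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-marker major-allele frequency p (q = 1 - p) with provenance tag.

    ``monomorphic`` flags markers with p in {0, 1}; downstream matrix
    builders refuse them (they must be filtered or were never emitted).
    """

    p: np.ndarray
    source: str = "training"

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def monomorphic(self) -> np.ndarray:
        return (self.p <= 0.0) | (self.p >= 1.0)

    @property
    def n_markers(self) -> int:
        return len(self.p)
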