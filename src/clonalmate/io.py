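"""Readers and writers for the package's plain-text dialects.

* genotype TSV: first column ``clone_id``, then one column per marker
  (header = marker ids), codes 0/1/2 and ``NA`` for missing;
* PLINK ``.raw`` dialect: FID IID PAT MAT SEX PHENOTYPE then dosage
  columns (space-separated);
* map TSV: ``marker_id  chromosome  position_morgan``;
* phenotype TSV: ``clone_id  trait  value``;
* GCTA binary GRM triplet: ``.grm.bin`` (float32 lower triangle,
  diagonal included, row-major), ``.grm.N.bin`` (float32 marker counts),
  ``.grm.id`` (FID IID);
* one-way VCF import of biallelic SNPs to major-allele dosages.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message carries the offending location."""


# ---------------------------------------------------------------- genotypes

def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.to_frame()
    df = df.replace(MISSING, pd.NA)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"clone_id": str})
    if df.columns[0] != "clone_id":
        raise ParseError(f"{path}: first column must be 'clone_id'")
    codes = df.iloc[:, 1:].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(clone_id=df["clone_id"].tolist(),
                          marker_id=df.columns[1:].to_numpy(dtype=str),
                          codes=codes)


def write_plink_raw(genotypes: GenotypeMatrix, path,
                    phenotype: np.ndarray | None = None) -> None:
    df = pd.DataFrame({
        "FID": genotypes.clone_id,
        "IID": genotypes.clone_id,
        "PAT": 0, "MAT": 0, "SEX": 0,
        "PHENOTYPE": (-9 if phenotype is None else phenotype),
    })
    dosages = pd.DataFrame(genotypes.codes, columns=genotypes.marker_id)
    dosages = dosages.replace(MISSING, pd.NA)
    pd.concat([df, dosages], axis=1).to_csv(path, sep=" ", index=False,
                                            na_rep="NA")


def read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", dtype={"IID": str, "FID": str})
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != meta:
        raise ParseError(f"{path}: missing PLINK .raw header columns")
    codes = df.iloc[:, 6:].to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    return GenotypeMatrix(clone_id=df["IID"].tolist(),
                          marker_id=df.columns[6:].to_numpy(dtype=str),
                          codes=codes)


# ---------------------------------------------------------------------- map

def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "chromosome", "position_morgan"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    for c, sub in df.groupby("chromosome"):
        bad = np.flatnonzero(np.diff(sub["position_morgan"].to_numpy()) <= 0)
        if len(bad):
            marker = sub["marker_id"].iloc[bad[0] + 1]
            raise ParseError(
                f"{path}: non-monotone position at marker {marker} "
                f"(chromosome {c}, line {sub.index[bad[0] + 1] + 2})")
    lengths = {int(c): float(sub["position_morgan"].max())
               for c, sub in df.groupby("chromosome")}
    return GeneticMap(marker_id=df["marker_id"].to_numpy(dtype=str),
                      chromosome=df["chromosome"].to_numpy(dtype=int),
                      position=df["position_morgan"].to_numpy(dtype=float),
                      chromosome_length=lengths)


# --------------------------------------------------------------- phenotypes

def write_phenotypes_tsv(phenos: pd.DataFrame, path,
                         trait: str = "trait") -> None:
    out = pd.DataFrame({"clone_id": phenos["clone_id"],
                        "trait": trait,
                        "value": phenos["phenotype"]})
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"clone_id", "trait", "value"}.issubset(df.columns):
        raise ParseError(f"{path}: need clone_id/trait/value columns")
    return df


# ---------------------------------------------------------------- GCTA GRM

def write_gcta_grm(grm: np.ndarray, ids: list[str], prefix,
                   n_markers: int) -> None:
    """GCTA binary triplet (float32 lower triangle incl. diagonal)."""
    prefix = str(prefix)
    n = len(ids)
    tri = grm[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    np.full(tri.shape, n_markers, dtype="<f4").tofile(prefix + ".grm.N.bin")
    pd.DataFrame({"FID": ids, "IID": ids}).to_csv(
        prefix + ".grm.id", sep="\t", index=False, header=False)


def read_gcta_grm(prefix) -> tuple[np.ndarray, list[str], np.ndarray]:
    prefix = str(prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None)[1].tolist()
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if len(tri) != n * (n + 1) // 2:
        raise ParseError(f"{prefix}.grm.bin: wrong element count")
    grm = np.zeros((n, n))
    grm[np.tril_indices(n)] = tri
    grm = grm + np.tril(grm, -1).T
    counts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    return grm, ids, counts


def write_grm_tsv(grm: np.ndarray, ids: list[str], path) -> None:
    pd.DataFrame(grm, index=ids, columns=ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------- VCF

def read_vcf(path) -> tuple[GenotypeMatrix, int]:
    """Import biallelic SNPs from a VCF as major-allele dosages.

    Multiallelic records are skipped and counted (logged).  Returns the
    genotype matrix and the number of skipped records.  The major allele
    is whichever of REF/ALT is more frequent in the sample.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, columns = [], []
    skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (cyvcf2 convention
        # with gts012), 3/2=unknown depending on mode; use genotypes
        alt_dose = np.array(
            [(-1 if g[0] < 0 or g[1] < 0 else g[0] + g[1])
             for g in rec.genotypes], dtype=np.int8)
        obs = alt_dose >= 0
        if not obs.any():
            skipped += 1
            continue
        alt_freq = alt_dose[obs].mean() / 2.0
        col = alt_dose.copy()
        if alt_freq <= 0.5:   # REF is the major allele: flip to major dosage
            col[obs] = 2 - col[obs]
        marker_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        columns.append(col)
    if skipped:
        logger.info("VCF import: skipped %d non-biallelic/all-missing "
                    "records", skipped)
    codes = (np.stack(columns, axis=1) if columns
             else np.empty((len(samples), 0), dtype=np.int8))
    return (GenotypeMatrix(clone_id=samples,
                           marker_id=np.array(marker_ids, dtype=str),
                           codes=codes),
            skipped)


# ----------------------------------------------------------------- reports

def write_fit_json(varcomps, fit, path) -> None:
    """Model-fit report: variance components, SEs, logL, b-hat."""
    payload = {
        "model": fit.model,
        "variance_components": varcomps.components,
        "residual_variance": varcomps.residual,
        "standard_errors": varcomps.se,
        "residual_se": varcomps.residual_se,
        "boundary": varcomps.boundary,
        "log_likelihood": varcomps.log_likelihood,
        "n_iterations": varcomps.n_iterations,
        "b_hat": fit.b_hat,
        "beta_hat": fit.beta_hat.tolist(),
        "mme_residual": fit.mme_residual,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_predictions_tsv(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, sep="\t", index=False)
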