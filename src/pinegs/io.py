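"""File formats: CSV readers/writers for every pipeline container, VCF input.

All CSVs are RFC-4180, UTF-8; pipeline outputs start with a ``#`` comment
line naming the producing stage and the run digest so any file can be
traced back to one manifest.  Missing genotype calls are written as empty
fields and read back as ``NaN``.
"""
from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, Pedigree, RelationshipMatrix, UNKNOWN_PARENT


def _header_comment(stage: str | None, digest: str | None) -> str:
    if stage is None:
        return ""
    return f"# stage={stage} digest={digest or 'unset'}\n"


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes_csv(genotypes: GenotypeMatrix, path, stage=None, digest=None) -> None:
    df = pd.DataFrame(genotypes.dosages, index=genotypes.ids, columns=genotypes.markers)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(stage, digest))
        df.to_csv(fh, index_label="id", float_format="%.6g", na_rep="")


def read_genotypes_csv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, comment="#", index_col="id")
    return GenotypeMatrix(
        ids=df.index.to_numpy(dtype=object),
        markers=df.columns.to_numpy(dtype=object),
        dosages=df.to_numpy(dtype=np.float32),
    )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Biallelic records from a VCF; GT becomes alternate-allele dosage.

    Multi-allelic records are skipped with a counted warning; ``./.`` and
    half-calls become missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    markers, rows = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        markers.append(name)
        dosage = np.empty(len(ids), dtype=np.float32)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            dosage[i] = np.nan if len(alleles) < 2 else float(sum(alleles))
        rows.append(dosage)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic VCF records", stacklevel=2)
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(ids), 0), dtype=np.float32)
    )
    return GenotypeMatrix(
        ids=ids, markers=np.array(markers, dtype=object), dosages=dosages
    )


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    fmt = format or ("vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "csv")
    if fmt == "vcf":
        return read_genotypes_vcf(path)
    if fmt == "csv":
        return read_genotypes_csv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes_vcf(genotypes: GenotypeMatrix, path, stage=None) -> None:
    """Minimal unphased VCF 4.2 (abstract loci: CHROM=0, POS=index)."""
    lines = ["##fileformat=VCFv4.2",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if stage:
        lines.append(f"##source=pinegs:{stage}")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += list(genotypes.ids)
    lines.append("\t".join(header))
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, marker in enumerate(genotypes.markers):
        col = genotypes.dosages[:, j]
        gts = ["./." if np.isnan(v) else code[float(v)] for v in col]
        lines.append("\t".join(["0", str(j + 1), str(marker), "A", "B", ".", ".", ".", "GT"] + gts))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table_csv(df: pd.DataFrame, path, stage=None, digest=None, index=False) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(stage, digest))
        df.to_csv(fh, index=index, float_format="%.10g")


def read_table_csv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_pedigree_csv(pedigree: Pedigree, path, stage=None, digest=None) -> None:
    write_table_csv(pedigree.table[["id", "dam", "sire"]], path, stage, digest)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, comment="#", dtype=str).fillna(UNKNOWN_PARENT)
    return Pedigree(table=df)


def write_phenotypes_csv(phenotypes: pd.DataFrame, path, stage=None, digest=None) -> None:
    write_table_csv(phenotypes, path, stage, digest)


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# relationship matrices
# ---------------------------------------------------------------------------

def write_relationship_csv(matrix: RelationshipMatrix, path, stage=None, digest=None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_header_comment(stage, digest))
        fh.write(f"# kind={matrix.kind}\n")
        matrix.to_dataframe().to_csv(fh, index_label="id", float_format="%.10g")


def read_relationship_csv(path, kind: str | None = None) -> RelationshipMatrix:
    detected = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# kind="):
                detected = line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#", index_col="id")
    return RelationshipMatrix(
        ids=df.index.to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
        kind=kind or detected or "GRM",
    )


def write_relationship_long(matrix: RelationshipMatrix, path, stage=None, digest=None) -> None:
    """Lower-triangle long format (id1, id2, value) for animal-model tools."""
    ids = matrix.ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1):
            rows.append((ids[i], ids[j], matrix.values[i, j]))
    write_table_csv(pd.DataFrame(rows, columns=["id1", "id2", "value"]), path, stage, digest)
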