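"""Additive relationship matrices: pedigree NRM and VanRaden GRM.

The numerator relationship matrix (NRM) is the expected additive
relatedness implied by the recorded pedigree, built with the tabular
(recursive) method; progeny of one dam with unknown, unrelated sires come
out at the classical half-sib coefficient 0.25.  The genomic relationship
matrix (GRM) is the marker realization of the same quantity, VanRaden
method 1: ``G = ZZ' / (2 sum_j p_j (1 - p_j))`` with ``Z`` the dosage
matrix centered at twice the allele frequency estimated from the analyzed
sample.
"""
from __future__ import annotations

import numpy as np

from .datatypes import (
    GenotypeMatrix,
    Pedigree,
    RelationshipMatrix,
    UNKNOWN_PARENT,
    ValidationError,
)


def build_nrm(pedigree: Pedigree) -> RelationshipMatrix:
    """Tabular-method numerator relationship matrix.

    Recursions (unknown parent contributes 0, and all unknown parents are
    treated as a single unrelated, non-inbred base population)::

        a_ii = 1 + 0.5 * a(dam_i, sire_i)
        a_ij = 0.5 * (a(j, dam_i) + a(j, sire_i))      for j < i

    The pedigree must list parents before offspring (validated at
    construction time), which also rules out cycles.
    """
    table = pedigree.table
    ids = table["id"].to_numpy(dtype=object)
    n = len(ids)
    pos = {v: i for i, v in enumerate(ids)}

    def parent_index(parent) -> int:
        if parent == UNKNOWN_PARENT:
            return -1
        return pos[parent]

    dam_idx = np.array([parent_index(d) for d in table["dam"]], dtype=int)
    sire_idx = np.array([parent_index(s) for s in table["sire"]], dtype=int)

    A = np.zeros((n, n))
    for i in range(n):
        d, s = dam_idx[i], sire_idx[i]
        a_ds = A[d, s] if (d >= 0 and s >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_ds
        if i == 0:
            continue
        row_d = A[:i, d] if d >= 0 else 0.0
        row_s = A[:i, s] if s >= 0 else 0.0
        A[:i, i] = 0.5 * (row_d + row_s)
        A[i, :i] = A[:i, i]
    return RelationshipMatrix(ids=ids, values=A, kind="NRM")


def build_grm(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Requires complete dosages (impute first) and at least one polymorphic
    marker.  By default allele frequencies are estimated from the analyzed
    sample itself — then the rows and columns of ``G`` average to zero by
    construction, which deflates within-family coefficients relative to the
    pedigree expectation.  Pass ``freqs`` (per-marker alternate-allele
    frequencies of the base population, e.g. the founders) to center on a
    reference population instead; only then does the mean coefficient of a
    relative pair estimate the numerator relationship (0.25 half-sibs,
    0.5 parent-offspring).
    """
    if genotypes.missing_mask.any():
        raise ValidationError("GRM requires complete genotypes; run impute_missing first")
    M = genotypes.dosages.astype(np.float64)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (genotypes.n_markers,):
        raise ValidationError("freqs must provide one frequency per marker")
    het = 2.0 * np.sum(p * (1.0 - p))
    if het <= 0.0:
        raise ValidationError("all markers are monomorphic; GRM denominator is zero")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / het
    G = 0.5 * (G + G.T)  # exact symmetry against accumulated rounding
    return RelationshipMatrix(ids=genotypes.ids, values=G, kind="GRM")
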