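"""Numerator (pedigree) relationship matrix machinery.

Implements the tabular method for A (with exact inbreeding), Henderson's
rules for A^-1 accounting for inbreeding, and extraction of the
genotyped-subset block A22 used by the single-step H matrix.  All dense:
the populations this pipeline targets are at most a few thousand animals,
where dense recursions are simpler to verify than sparse ones.
"""

from __future__ import annotations

import numpy as np

from .datamodel import Pedigree, RelationshipMatrix

__all__ = ["a_matrix", "a_inverse", "inbreeding", "subset_a22"]


def a_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix A by the tabular method.

    For animal ``i`` with parents ``s``, ``d`` (earlier in the ordering):
    ``a(i,i) = 1 + a(s,d)/2`` and ``a(i,j) = [a(j,s) + a(j,d)] / 2`` for
    ``j < i``; an unknown parent contributes 0.  Diagonals are ``1 + F``
    with F the inbreeding coefficient.
    """
    n = ped.n_animals
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
    return RelationshipMatrix(animal_ids=ped.animal_ids, values=A)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F = diag(A) - 1, exact from the tabular A."""
    return np.diag(a_matrix(ped).values) - 1.0


def a_inverse(ped: Pedigree) -> np.ndarray:
    """Inverse of A by Henderson's rules with inbreeding.

    Each animal contributes alpha_i = 1 / m_i where m_i is its Mendelian
    sampling variance given parental inbreeding: 0.5 - 0.25 (F_s + F_d)
    with both parents known, 0.75 - 0.25 F_p with one, 1 with none.
    alpha_i is added at (i,i), -alpha_i/2 at (i,parent) and alpha_i/4 at
    each (parent,parent) pair.
    """
    n = ped.n_animals
    par = ped.parent_indices()
    F = inbreeding(ped)
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        known = [p for p in (s, d) if p >= 0]
        m = 1.0 - 0.25 * sum(1.0 + F[p] for p in known)
        alpha = 1.0 / m
        Ainv[i, i] += alpha
        for p in known:
            Ainv[i, p] -= alpha / 2.0
            Ainv[p, i] -= alpha / 2.0
        for p in known:
            for q in known:
                Ainv[p, q] += alpha / 4.0
    return Ainv


def subset_a22(A: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in the order
    given (which must match the GenotypeSet animal order)."""
    lookup = {a: i for i, a in enumerate(A.animal_ids)}
    try:
        idx = np.array([lookup[a] for a in genotyped_ids], dtype=np.intp)
    except KeyError as exc:
        raise KeyError(f"genotyped animal {exc.args[0]!r} not in relationship matrix") from None
    return RelationshipMatrix(
        animal_ids=list(genotyped_ids),
        values=A.values[np.ix_(idx, idx)].copy(),
    )
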