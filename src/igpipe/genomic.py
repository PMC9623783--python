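"""Genomic relationship machinery.

Allele frequencies, genotype centering, the VanRaden genomic relationship
matrix G = ZZ'/k with k = 2 sum p_j (1 - p_j) and optional blending toward
A22 (or the identity), the sparse APY inverse of G built from a directly
inverted core block, and an eigenvalue-based estimator of the core size
needed to capture a given fraction of the variation in G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import invert_dense_psd
from .population import MISSING_CODE, GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "GenomicRelationship",
    "ApyInverse",
    "allele_frequencies",
    "center_genotypes",
    "build_G",
    "apy_inverse",
    "estimate_core_size",
]


@dataclass
class AlleleFrequencies:
    """Counted-allele frequencies per marker, and the ids they came from."""

    p: np.ndarray
    source_ids: np.ndarray
    monomorphic: np.ndarray = field(init=False)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.source_ids = np.asarray(self.source_ids, dtype=np.int64)
        self.monomorphic = (self.p <= 0.0) | (self.p >= 1.0)

    @property
    def scaling_k(self) -> float:
        """k = 2 sum_j p_j (1 - p_j), the VanRaden denominator."""
        return float(2.0 * np.sum(self.p * (1.0 - self.p)))


def allele_frequencies(geno: GenotypeMatrix, ids=None) -> AlleleFrequencies:
    """Frequencies of the counted allele, excluding missing calls.

    ``p_j = sum(codes_j) / (2 * n_nonmissing_j)`` over the animals in ``ids``
    (all genotyped animals by default). A marker with no non-missing call in
    the chosen set is an error.
    """
    if ids is None:
        ids = geno.ids
    codes = geno.codes[geno.rows(ids)]
    obs = codes != MISSING_CODE
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = np.flatnonzero(n_obs == 0)
        raise ValueError(f"markers with all calls missing: {geno.marker_ids[bad][:10].tolist()}")
    total = np.where(obs, codes, 0).sum(axis=0, dtype=np.int64)
    return AlleleFrequencies(total / (2.0 * n_obs), ids)


def center_genotypes(geno: GenotypeMatrix, freqs: AlleleFrequencies, ids=None) -> np.ndarray:
    """Centered gene-content matrix Z with z_ij = m_ij - 2 p_j.

    Missing calls are imputed at the population mean (2 p_j), i.e. contribute
    zero after centering.
    """
    if ids is None:
        ids = geno.ids
    codes = geno.codes[geno.rows(ids)]
    if freqs.p.size != geno.n_markers:
        raise ValueError("frequency vector does not cover the marker panel")
    Z = codes.astype(float)
    miss = codes == MISSING_CODE
    if miss.any():
        Z[miss] = np.broadcast_to(2.0 * freqs.p, Z.shape)[miss]
    Z -= 2.0 * freqs.p
    return Z


@dataclass
class GenomicRelationship:
    """Dense genomic relationship matrix with its scaling and blending."""

    ids: np.ndarray
    matrix: np.ndarray
    k: float
    beta: float

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.ids.size, self.ids.size):
            raise ValueError("G shape does not match id count")

    @property
    def n_animals(self) -> int:
        return self.ids.size


def build_G(
    Z: np.ndarray,
    freqs: AlleleFrequencies,
    ids,
    blend_beta: float = 0.05,
    A22: np.ndarray | None = None,
) -> GenomicRelationship:
    """VanRaden genomic relationship G = (1-beta) ZZ'/k + beta * A22.

    ``A22`` defaults to the identity when no pedigree submatrix is supplied.
    Blending keeps G invertible when animals outnumber markers or genotypes
    are duplicated; ``beta`` is recorded on the result.
    """
    k = freqs.scaling_k
    if k <= 0:
        raise ValueError("all markers monomorphic: scaling k = 2*sum p(1-p) is zero")
    if not 0.0 <= blend_beta < 1.0:
        raise ValueError("blend_beta must be in [0, 1)")
    G = (Z @ Z.T) / k
    if blend_beta > 0.0:
        target = np.eye(G.shape[0]) if A22 is None else np.asarray(A22, dtype=float)
        if target.shape != G.shape:
            raise ValueError("A22 shape does not match the animal set")
        G = (1.0 - blend_beta) * G + blend_beta * target
    return GenomicRelationship(np.asarray(ids), 0.5 * (G + G.T), k, blend_beta)


class ApyInverse:
    """Sparse-structured inverse of G from the proven-and-young recursion.

    Core animals get a direct dense inverse of their block G_cc; each noncore
    animal couples to the core only, through P = G_nc G_cc^-1 and its
    conditional variance m_i = g_ii - g_ic G_cc^-1 g_ci. The implied inverse

        [[G_cc^-1 + P' M^-1 P,  -P' M^-1],
         [-M^-1 P,               M^-1   ]]

    is never formed densely between noncore animals; only matrix-vector
    products and the diagonal are exposed.
    """

    def __init__(self, ids, core_pos, noncore_pos, Gcc_inv, P, m):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.core_pos = np.asarray(core_pos, dtype=np.int64)
        self.noncore_pos = np.asarray(noncore_pos, dtype=np.int64)
        self.Gcc_inv = Gcc_inv
        self.P = P  # (n_noncore, n_core)
        self.m = m  # (n_noncore,)

    @property
    def core_ids(self) -> np.ndarray:
        return self.ids[self.core_pos]

    @property
    def noncore_ids(self) -> np.ndarray:
        return self.ids[self.noncore_pos]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """G_APY^-1 @ v for v ordered like ``ids`` (vector or matrix)."""
        v = np.asarray(v, dtype=float)
        vc = v[self.core_pos]
        vn = v[self.noncore_pos]
        if self.m.size:
            minv = 1.0 / self.m
            resid = (self.P @ vc - vn) * (minv[:, None] if v.ndim == 2 else minv)
            out_c = self.Gcc_inv @ vc + self.P.T @ resid
            out_n = -resid
        else:
            out_c = self.Gcc_inv @ vc
            out_n = vn[:0]
        out = np.empty_like(v)
        out[self.core_pos] = out_c
        out[self.noncore_pos] = out_n
        return out

    __call__ = matvec

    def diagonal(self) -> np.ndarray:
        diag = np.empty(self.ids.size)
        core_diag = np.diag(self.Gcc_inv).copy()
        if self.m.size:
            core_diag += np.einsum("ij,ij->j", self.P, self.P / self.m[:, None])
            diag[self.noncore_pos] = 1.0 / self.m
        diag[self.core_pos] = core_diag
        return diag

    def dense(self) -> np.ndarray:
        """Assemble the full implied inverse (tests / small cases only)."""
        n = self.ids.size
        out = np.zeros((n, n))
        cc = self.Gcc_inv.copy()
        if self.m.size:
            Pm = self.P / self.m[:, None]
            cc = cc + self.P.T @ Pm
            out[np.ix_(self.core_pos, self.noncore_pos)] = -Pm.T
            out[np.ix_(self.noncore_pos, self.core_pos)] = -Pm
            out[self.noncore_pos, self.noncore_pos] = 1.0 / self.m
        out[np.ix_(self.core_pos, self.core_pos)] = cc
        return out


def apy_inverse(G: GenomicRelationship, core_ids, m_floor: float = 1e-8) -> ApyInverse:
    """APY inverse of G given a set of core animal ids.

    Errors if a noncore animal's conditional variance m_i falls at or below
    ``m_floor`` (a genotype fully explained by the core, e.g. a duplicate).
    """
    core_ids = np.asarray(core_ids, dtype=np.int64)
    if core_ids.size == 0:
        raise ValueError("core set is empty")
    idx = {a: i for i, a in enumerate(G.ids)}
    try:
        core_pos = np.array([idx[a] for a in core_ids], dtype=np.int64)
    except KeyError as e:
        raise KeyError(f"core id {e.args[0]} not among G's animals")
    mask = np.ones(G.n_animals, dtype=bool)
    mask[core_pos] = False
    noncore_pos = np.flatnonzero(mask)
    Gcc = G.matrix[np.ix_(core_pos, core_pos)]
    Gcc_inv = invert_dense_psd(Gcc)
    Gnc = G.matrix[np.ix_(noncore_pos, core_pos)]
    P = Gnc @ Gcc_inv
    m = G.matrix[noncore_pos, noncore_pos] - np.einsum("ij,ij->i", P, Gnc)
    if (m <= m_floor).any():
        bad = G.ids[noncore_pos[m <= m_floor]]
        raise ValueError(
            f"noncore animals fully explained by the core (m_ii <= {m_floor:g}): {bad[:5].tolist()}"
        )
    return ApyInverse(G.ids, core_pos, noncore_pos, Gcc_inv, P, m)


def estimate_core_size(G: GenomicRelationship, threshold: float = 0.98) -> int:
    """Smallest k with the top-k eigenvalues summing to >= threshold * trace(G).

    The number of large eigenvalues of G approximates the number of
    independent chromosome segments, and hence an adequate APY core size.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    eig = np.linalg.eigvalsh(G.matrix)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total <= 0:
        raise ValueError("G has no positive eigenvalues")
    frac = np.cumsum(eig) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)
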