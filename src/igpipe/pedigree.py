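"""Pedigree-based relationship machinery.

Implements the numerator relationship matrix A by the tabular method,
inbreeding coefficients from its diagonal, Henderson's recursive rules for
the sparse A inverse (with inbreeding), and a dense symmetric-positive-
definite inverter used for A22 and for direct G inversion at desk scale.

Unknown parents are treated as unrelated, non-inbred base animals; no
unknown-parent groups are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from numba import njit

from .population import Pedigree

__all__ = [
    "InbreedingVector",
    "compute_inbreeding",
    "build_A",
    "build_A_inverse",
    "invert_dense_psd",
    "tabular_A_kernel",
]


@dataclass
class InbreedingVector:
    """Per-animal inbreeding coefficients F (pedigree order)."""

    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)


@njit(cache=True)
def tabular_A_kernel(sire_idx, dam_idx):  # pragma: no cover - numba kernel
    """Tabular recursion for A: a_ij = (a_i,s(j) + a_i,d(j))/2, a_ii = 1 + F_i.

    Parent indices are 0-based positions sorted parents-first; -1 = unknown.
    """
    n = sire_idx.size
    A = np.zeros((n, n))
    for i in range(n):
        s = sire_idx[i]
        d = dam_idx[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[j, s]
            if d >= 0:
                v += 0.5 * A[j, d]
            A[i, j] = v
            A[j, i] = v
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
    return A


def build_A(ped: Pedigree, subset=None) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    Parameters
    ----------
    ped
        Pedigree (sorted parents-first internally).
    subset
        Optional iterable of animal ids; the full recursion is run over the
        whole pedigree and the result restricted to these rows/columns (in
        the order given). With ``subset`` equal to the genotyped animals this
        yields A22.
    """
    A = tabular_A_kernel(ped.sire_idx, ped.dam_idx)
    if subset is None:
        return A
    pos = ped.positions(subset)
    return A[np.ix_(pos, pos)]


def compute_inbreeding(ped: Pedigree) -> InbreedingVector:
    """Inbreeding coefficients F_i = a(sire_i, dam_i)/2 via the tabular A.

    Animals with an unknown parent get F = 0. Desk-scale implementation:
    materialises the full A (fine up to a few tens of thousands of animals).
    """
    A = tabular_A_kernel(ped.sire_idx, ped.dam_idx)
    return InbreedingVector(ped.ids, np.diag(A) - 1.0)


def build_A_inverse(ped: Pedigree, F: InbreedingVector | None = None) -> sp.csr_matrix:
    """Sparse A inverse by Henderson's recursive rules with inbreeding.

    For animal i with Mendelian-sampling variance fraction
    m_i = 0.5 - 0.25 (F_s + F_d) (both parents known; 0.75 - 0.25 F_p with
    one, 1 with none), let d_i = 1/m_i. Contributions: d_i to (i,i),
    -d_i/2 to (i, parent), d_i/4 to (parent, parent').
    """
    if F is None:
        F = compute_inbreeding(ped)
    if F.values.size != ped.n_animals:
        raise ValueError("inbreeding vector does not cover the pedigree")
    n = ped.n_animals
    s, d = ped.sire_idx, ped.dam_idx
    Fs = np.where(s >= 0, F.values[np.maximum(s, 0)], np.nan)
    Fd = np.where(d >= 0, F.values[np.maximum(d, 0)], np.nan)
    m = np.full(n, 1.0)
    both = (s >= 0) & (d >= 0)
    sire_only = (s >= 0) & (d < 0)
    dam_only = (s < 0) & (d >= 0)
    m[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    m[sire_only] = 0.75 - 0.25 * Fs[sire_only]
    m[dam_only] = 0.75 - 0.25 * Fd[dam_only]
    di = 1.0 / m

    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [di]
    for p in (s, d):
        k = p >= 0
        rows.append(np.arange(n)[k])
        cols.append(p[k])
        vals.append(-0.5 * di[k])
        rows.append(p[k])
        cols.append(np.arange(n)[k])
        vals.append(-0.5 * di[k])
        rows.append(p[k])
        cols.append(p[k])
        vals.append(0.25 * di[k])
    # cross parent-parent' terms
    k = both
    for a, b in ((s, d), (d, s)):
        rows.append(a[k])
        cols.append(b[k])
        vals.append(0.25 * di[k])
    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    return Ainv


def invert_dense_psd(matrix: np.ndarray) -> np.ndarray:
    """Invert a dense symmetric positive-definite matrix via Cholesky.

    Raises ``np.linalg.LinAlgError`` reporting the smallest eigenvalue (and
    suggesting blending toward a PD target) if the factorization fails.
    The returned inverse is symmetrised.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    try:
        c, low = scipy.linalg.cho_factor(matrix, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        lam_min = float(scipy.linalg.eigvalsh(matrix, subset_by_index=[0, 0])[0])
        raise np.linalg.LinAlgError(
            f"matrix is not positive definite (smallest eigenvalue {lam_min:.3e}); "
            "consider blending toward a positive-definite target"
        )
    inv = scipy.linalg.cho_solve((c, low), np.eye(matrix.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)
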