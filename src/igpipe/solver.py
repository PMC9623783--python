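"""Single-step GBLUP mixed-model machinery.

Assembles the combined relationship inverse H^-1 = A^-1 + [0; G^-1 - A22^-1]
as a matrix-free linear operator, builds the (multi-)trait repeatability
animal-model mixed model equations as matvec contracts, solves them with a
preconditioned conjugate gradient (block-diagonal preconditioner, zero start
vector), and orchestrates the whole single-step evaluation.

Unknowns are ordered entity-major: fixed-effect levels, then animals, then
permanent-environment terms, each carrying a contiguous block of n_traits
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic import ApyInverse, GenomicRelationship, allele_frequencies, apy_inverse, build_G, center_genotypes
from .pedigree import build_A, build_A_inverse, compute_inbreeding, invert_dense_psd
from .population import GenotypeMatrix, Pedigree, PhenotypeRecords

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "ModelSpec",
    "BreedingValues",
    "HInverseOperator",
    "assemble_H_inverse",
    "MixedModelSystem",
    "build_mme",
    "PcgResult",
    "pcg_solve",
    "SolveOptions",
    "SsgblupResult",
    "run_ssgblup",
]


@dataclass
class VarianceComponents:
    """Additive, residual and permanent-environment (co)variance matrices.

    All are n_traits x n_traits; the additive matrix must be positive
    definite, the others positive semi-definite. The marker-effect variance
    implied by a genomic scaling k is sigma_u^2 = sigma_a^2 / k, so the
    backsolving ratio lambda = sigma_u^2 / sigma_a^2 = 1/k.
    """

    additive: np.ndarray
    residual: np.ndarray
    permanent_env: np.ndarray | None = None

    def __post_init__(self):
        self.additive = np.atleast_2d(np.asarray(self.additive, dtype=float))
        self.residual = np.atleast_2d(np.asarray(self.residual, dtype=float))
        t = self.additive.shape[0]
        if self.permanent_env is None:
            self.permanent_env = np.zeros((t, t))
        self.permanent_env = np.atleast_2d(np.asarray(self.permanent_env, dtype=float))
        for name, M in (("additive", self.additive), ("residual", self.residual), ("permanent_env", self.permanent_env)):
            if M.shape != (t, t) or not np.allclose(M, M.T):
                raise ValueError(f"{name} covariance must be symmetric {t}x{t}")
            if np.linalg.eigvalsh(M)[0] < -1e-10:
                raise ValueError(f"{name} covariance is not positive semi-definite")
        if np.linalg.eigvalsh(self.additive)[0] <= 0:
            raise ValueError("additive covariance must be positive definite")

    @classmethod
    def from_scalars(cls, sigma2_a, sigma2_e, sigma2_pe=0.0) -> "VarianceComponents":
        return cls(np.atleast_2d(sigma2_a), np.atleast_2d(sigma2_e), np.atleast_2d(sigma2_pe))

    @property
    def n_traits(self) -> int:
        return self.additive.shape[0]

    @property
    def has_pe(self) -> bool:
        return bool(np.any(np.diag(self.permanent_env) > 0))

    def genetic_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.additive))

    def marker_lambda(self, k: float) -> float:
        """lambda = sigma_u^2 / sigma_a^2 = 1/k under the VanRaden scaling."""
        return 1.0 / k


@dataclass
class ModelSpec:
    """Animal-model specification: trait count, the single fixed factor
    (contemporary group, column ``fixed_level``), and whether a permanent-
    environment effect is fitted (required for repeated records)."""

    n_traits: int = 1
    fit_pe: bool | None = None  # None: fit iff the PE variance is nonzero

    def resolve_pe(self, vc: VarianceComponents) -> bool:
        return vc.has_pe if self.fit_pe is None else self.fit_pe


@dataclass
class BreedingValues:
    """Estimated breeding values per animal and trait."""

    ids: np.ndarray
    values: np.ndarray  # (n_animals, n_traits)
    source: str = "gebv"

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.ids.size:
            self.values = self.values.T
        self._index = pd.Index(self.ids)

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def for_ids(self, ids) -> np.ndarray:
        pos = self._index.get_indexer(np.asarray(ids, dtype=np.int64))
        if (pos < 0).any():
            bad = np.asarray(ids)[pos < 0][0]
            raise KeyError(f"no breeding value for animal {bad}")
        return self.values[pos]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"t{j}" for j in range(self.n_traits)])
        df.insert(0, "id", self.ids)
        df["source"] = self.source
        return df


class HInverseOperator:
    """Matrix-free H^-1: pedigree inverse everywhere, plus the genomic
    correction G^-1 - A22^-1 scattered onto the genotyped positions."""

    def __init__(self, Ainv: sp.spmatrix, geno_pos=None, Ginv=None, A22inv=None):
        self.Ainv = Ainv.tocsr()
        self.n = Ainv.shape[0]
        self.geno_pos = None if geno_pos is None else np.asarray(geno_pos, dtype=np.int64)
        self.Ginv = Ginv
        self.A22inv = A22inv
        if self.geno_pos is not None and Ginv is not None:
            ng = self.geno_pos.size
            gdim = Ginv.ids.size if isinstance(Ginv, ApyInverse) else Ginv.shape[0]
            if gdim != ng or A22inv.shape[0] != ng:
                raise ValueError(
                    f"genomic blocks ({gdim} / {A22inv.shape[0]}) do not match the {ng} genotyped animals"
                )

    @property
    def genomic(self) -> bool:
        return self.geno_pos is not None and self.Ginv is not None

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.Ainv @ v
        if self.genomic:
            v22 = v[self.geno_pos]
            gv = self.Ginv.matvec(v22) if isinstance(self.Ginv, ApyInverse) else self.Ginv @ v22
            out[self.geno_pos] += gv - self.A22inv @ v22
        return out

    __call__ = matvec

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.Ainv.diagonal()).copy()
        if self.genomic:
            gd = self.Ginv.diagonal() if isinstance(self.Ginv, ApyInverse) else np.diag(self.Ginv)
            d[self.geno_pos] += gd - np.diag(self.A22inv)
        return d

    def dense(self) -> np.ndarray:
        """Assemble densely (small cases / oracle tests only)."""
        H = self.Ainv.toarray()
        if self.genomic:
            G = self.Ginv.dense() if isinstance(self.Ginv, ApyInverse) else self.Ginv
            H[np.ix_(self.geno_pos, self.geno_pos)] += G - self.A22inv
        return H


def assemble_H_inverse(Ainv, Ginv=None, A22inv=None, geno_pos=None) -> HInverseOperator:
    """Wrap the three inverses into the matrix-free H^-1 contract.

    ``geno_pos`` are 0-based pedigree positions of the genotyped animals, in
    the row order of ``Ginv``/``A22inv``. With no genomic part this is plain
    pedigree BLUP's A^-1.
    """
    return HInverseOperator(Ainv, geno_pos, Ginv, A22inv)


def _batch_inv(blocks: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(blocks)
    except np.linalg.LinAlgError:
        out = np.empty_like(blocks)
        for i, B in enumerate(blocks):
            try:
                out[i] = np.linalg.inv(B)
            except np.linalg.LinAlgError:
                out[i] = np.linalg.pinv(B)
        return out


class MixedModelSystem:
    """Matvec/rhs/preconditioner contract for the repeatability animal model.

    Equations (entity-major blocks of n_traits each):
    fixed-effect levels  |  animals (additive, against H^-1 (x) Sigma_a^-1)
    |  permanent-environment terms for recorded animals.

    Records with missing traits are handled by grouping records on their
    observed-trait pattern and using the inverse of the corresponding
    residual-covariance submatrix, embedded back into trait space.
    """

    def __init__(self, phen: PhenotypeRecords, ped: Pedigree, model: ModelSpec, vc: VarianceComponents, Hinv: HInverseOperator):
        t = model.n_traits
        if vc.n_traits != t:
            raise ValueError("variance components do not match the trait count")
        self.t = t
        self.ped = ped
        self.Hinv = Hinv
        self.vc = vc
        self.fit_pe = model.resolve_pe(vc)
        if self.fit_pe and np.linalg.eigvalsh(vc.permanent_env)[0] <= 0:
            raise ValueError("permanent-environment covariance must be positive definite to fit PE")
        self.Sa_inv = np.linalg.inv(vc.additive)
        self.Spe_inv = np.linalg.inv(vc.permanent_env) if self.fit_pe else None

        wide = phen.wide(t)
        bad = ~np.isin(wide["id"].to_numpy(dtype=np.int64), ped.ids) if len(wide) else np.zeros(0, bool)
        if bad.any():
            raise KeyError(f"phenotyped animal {wide['id'].to_numpy()[bad][0]} not in pedigree")
        self.Y = wide[[f"t{j}" for j in range(t)]].to_numpy(dtype=float) if len(wide) else np.zeros((0, t))
        levels, self.level_idx = np.unique(wide["fixed_level"].to_numpy(), return_inverse=True) if len(wide) else (np.array([]), np.zeros(0, np.int64))
        self.levels = levels
        self.animal_pos = ped.positions(wide["id"].to_numpy(dtype=np.int64)) if len(wide) else np.zeros(0, np.int64)
        pe_animals, self.pe_idx = np.unique(self.animal_pos, return_inverse=True)
        self.pe_animal_pos = pe_animals if self.fit_pe else np.zeros(0, np.int64)
        if not self.fit_pe:
            self.pe_idx = None

        obs = ~np.isnan(self.Y)
        if len(self.Y) and not obs.any(axis=1).all():
            raise ValueError("records with no observed trait are not allowed")
        self._patterns = []
        if len(self.Y):
            keys = obs @ (1 << np.arange(t))
            for key in np.unique(keys):
                rows = np.flatnonzero(keys == key)
                O = np.flatnonzero(obs[rows[0]])
                E = np.zeros((t, t))
                E[np.ix_(O, O)] = np.linalg.inv(vc.residual[np.ix_(O, O)])
                self._patterns.append((rows, E))
        self.Y0 = np.nan_to_num(self.Y)

        self.n_levels = self.levels.size
        self.n_animals = ped.n_animals
        self.n_pe = self.pe_animal_pos.size
        self.n_equations = (self.n_levels + self.n_animals + self.n_pe) * t
        self._rhs = self._build_rhs()
        self._precond = self._build_precond()

    # -- vector layout -------------------------------------------------
    def split(self, x: np.ndarray):
        t = self.t
        nb = self.n_levels * t
        na = self.n_animals * t
        beta = x[:nb].reshape(self.n_levels, t)
        a = x[nb : nb + na].reshape(self.n_animals, t)
        p = x[nb + na :].reshape(self.n_pe, t)
        return beta, a, p

    def join(self, beta, a, p) -> np.ndarray:
        return np.concatenate([beta.ravel(), a.ravel(), p.ravel()])

    # -- system contract ----------------------------------------------
    @property
    def rhs(self) -> np.ndarray:
        return self._rhs

    def _build_rhs(self) -> np.ndarray:
        beta = np.zeros((self.n_levels, self.t))
        a = np.zeros((self.n_animals, self.t))
        p = np.zeros((self.n_pe, self.t))
        for rows, E in self._patterns:
            T = self.Y0[rows] @ E
            np.add.at(beta, self.level_idx[rows], T)
            np.add.at(a, self.animal_pos[rows], T)
            if self.fit_pe:
                np.add.at(p, self.pe_idx[rows], T)
        return self.join(beta, a, p)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        beta, a, p = self.split(x)
        out_b = np.zeros_like(beta)
        out_a = self.Hinv.matvec(a) @ self.Sa_inv
        out_p = p @ self.Spe_inv if self.fit_pe else np.zeros_like(p)
        for rows, E in self._patterns:
            S = beta[self.level_idx[rows]] + a[self.animal_pos[rows]]
            if self.fit_pe:
                S = S + p[self.pe_idx[rows]]
            T = S @ E
            np.add.at(out_b, self.level_idx[rows], T)
            np.add.at(out_a, self.animal_pos[rows], T)
            if self.fit_pe:
                np.add.at(out_p, self.pe_idx[rows], T)
        return self.join(out_b, out_a, out_p)

    __call__ = matvec

    def _build_precond(self):
        t = self.t
        Bb = np.zeros((self.n_levels, t, t))
        Ba = np.tile(self.Sa_inv, (self.n_animals, 1, 1)) * self.Hinv.diagonal()[:, None, None]
        Bp = np.tile(self.Spe_inv, (self.n_pe, 1, 1)) if self.fit_pe else np.zeros((0, t, t))
        for rows, E in self._patterns:
            np.add.at(Bb, self.level_idx[rows], np.broadcast_to(E, (rows.size, t, t)))
            np.add.at(Ba, self.animal_pos[rows], np.broadcast_to(E, (rows.size, t, t)))
            if self.fit_pe:
                np.add.at(Bp, self.pe_idx[rows], np.broadcast_to(E, (rows.size, t, t)))
        return tuple(_batch_inv(B) if B.size else B for B in (Bb, Ba, Bp))

    def apply_precond(self, r: np.ndarray) -> np.ndarray:
        beta, a, p = self.split(r)
        Bb, Ba, Bp = self._precond
        zb = np.einsum("nij,nj->ni", Bb, beta) if beta.size else beta
        za = np.einsum("nij,nj->ni", Ba, a)
        zp = np.einsum("nij,nj->ni", Bp, p) if p.size else p
        return self.join(zb, za, zp)

    def dense(self) -> np.ndarray:
        """Assemble the coefficient matrix densely (oracle tests only)."""
        n = self.n_equations
        C = np.empty((n, n))
        e = np.zeros(n)
        for j in range(n):
            e[:] = 0.0
            e[j] = 1.0
            C[:, j] = self.matvec(e)
        return C


def build_mme(
    phen: PhenotypeRecords,
    ped: Pedigree,
    model: ModelSpec,
    vc: VarianceComponents,
    Hinv: HInverseOperator,
) -> MixedModelSystem:
    """Build the mixed-model-equation contract (matvec, rhs, preconditioner)."""
    return MixedModelSystem(phen, ped, model, vc, Hinv)


@dataclass
class PcgResult:
    x: np.ndarray
    iterations: int
    converged: bool
    final_criterion: float


def pcg_solve(A, b, M=None, tol: float = 1e-12, max_iter: int = 5000) -> PcgResult:
    """Preconditioned conjugate gradients with a zero start vector.

    ``A`` and ``M`` (the preconditioner inverse) are callables or matrices.
    Iterates until the squared relative residual  c = ||b - A x||^2 / ||b||^2
    drops to ``tol`` or ``max_iter`` is reached (the result then carries a
    non-convergence flag). Fully deterministic.
    """
    matvec = A if callable(A) else (lambda v: A @ v)
    prec = (lambda v: v) if M is None else (M if callable(M) else (lambda v: M @ v))
    b = np.asarray(b, dtype=float)
    bb = float(b @ b)
    x = np.zeros_like(b)
    if bb == 0.0:
        return PcgResult(x, 0, True, 0.0)
    r = b.copy()
    z = prec(r)
    p = z.copy()
    rz = float(r @ z)
    c = float(r @ r) / bb
    it = 0
    while c > tol and it < max_iter:
        Ap = matvec(p)
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        c = float(r @ r) / bb
        it += 1
        if c <= tol:
            break
        z = prec(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    return PcgResult(x, it, c <= tol, c)


@dataclass
class SolveOptions:
    """Tunables of a single-step solve."""

    blend_beta: float = 0.05
    genomic: bool = True
    apy_core_ids: np.ndarray | None = None
    tol: float = 1e-12
    max_iter: int = 5000


@dataclass
class SsgblupResult:
    gebv: BreedingValues
    fixed_effects: pd.DataFrame
    pe: pd.DataFrame | None
    iterations: int
    converged: bool
    final_criterion: float
    freqs: object | None = None
    scaling_k: float | None = None
    blend_beta: float | None = None
    system_size: int = 0


def run_ssgblup(
    ped: Pedigree,
    geno: GenotypeMatrix | None,
    phen: PhenotypeRecords,
    vc: VarianceComponents,
    model: ModelSpec | None = None,
    options: SolveOptions | None = None,
    freqs=None,
    G: GenomicRelationship | None = None,
    cache: dict | None = None,
) -> SsgblupResult:
    """Full single-step evaluation: relationship inverses, MME, PCG solve.

    With ``options.genomic`` False (or no genotypes) this is pedigree BLUP.
    ``freqs`` allows reusing allele frequencies from a wider pool than the
    genotypes passed in (so centered contents stay on one scale across
    stages); ``G`` allows injecting a pre-built genomic relationship;
    ``cache`` may carry ``"A_full"``/``"Ainv"``/``"F"`` across repeated solves
    on the same pedigree.
    """
    model = model or ModelSpec(n_traits=vc.n_traits)
    options = options or SolveOptions()
    cache = cache if cache is not None else {}

    if "Ainv" not in cache:
        F = cache.get("F") or compute_inbreeding(ped)
        cache["F"] = F
        cache["Ainv"] = build_A_inverse(ped, F)
    Ainv = cache["Ainv"]

    Ginv = A22inv = geno_pos = None
    k = beta = None
    if options.genomic and geno is not None and geno.n_animals:
        geno_pos = ped.positions(geno.ids)
        if "A_full" in cache:
            A22 = cache["A_full"][np.ix_(geno_pos, geno_pos)]
        else:
            A22 = build_A(ped, geno.ids)
        A22inv = invert_dense_psd(A22)
        if G is None:
            freqs = freqs or allele_frequencies(geno)
            Z = center_genotypes(geno, freqs, geno.ids)
            G = build_G(Z, freqs, geno.ids, options.blend_beta, A22)
        if not np.array_equal(G.ids, geno.ids):
            raise ValueError("G's animal order does not match the genotype matrix")
        k, beta = G.k, G.beta
        if options.apy_core_ids is not None:
            Ginv = apy_inverse(G, options.apy_core_ids)
        else:
            Ginv = invert_dense_psd(G.matrix)

    Hinv = assemble_H_inverse(Ainv, Ginv, A22inv, geno_pos)
    system = build_mme(phen, ped, model, vc, Hinv)
    res = pcg_solve(system.matvec, system.rhs, system.apply_precond, options.tol, options.max_iter)
    if not res.converged:
        logger.warning("PCG stopped at max_iter=%d with criterion %.3e", options.max_iter, res.final_criterion)
    beta_hat, a_hat, p_hat = system.split(res.x)

    fixed = pd.DataFrame(beta_hat, columns=[f"t{j}" for j in range(system.t)])
    fixed.insert(0, "fixed_level", system.levels)
    pe_df = None
    if system.fit_pe:
        pe_df = pd.DataFrame(p_hat, columns=[f"t{j}" for j in range(system.t)])
        pe_df.insert(0, "id", ped.ids[system.pe_animal_pos])
    return SsgblupResult(
        gebv=BreedingValues(ped.ids, a_hat, source="gebv" if Hinv.genomic else "pblup"),
        fixed_effects=fixed,
        pe=pe_df,
        iterations=res.iterations,
        converged=res.converged,
        final_criterion=res.final_criterion,
        freqs=freqs,
        scaling_k=k,
        blend_beta=beta,
        system_size=system.n_equations,
    )
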