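"""SNP marker effects backsolved from GEBV.

Converts breeding values of a (sub)set of genotyped animals into per-marker
effects via  u = lambda D Z' G^-1 a  with D = I and lambda = sigma_u^2 /
sigma_a^2 = 1/k under the VanRaden scaling. The subset's G is built from the
same pool allele frequencies as every other stage and inverted directly (at
subset sizes no sparse approximation is needed); a small blend toward the
identity keeps it invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic import AlleleFrequencies, build_G
from .pedigree import invert_dense_psd
from .solver import BreedingValues

__all__ = ["SnpEffects", "select_backsolve_subset", "backsolve_snp_effects"]


@dataclass
class SnpEffects:
    """Backsolved marker effects and the exact scaling used to produce them."""

    effects: np.ndarray  # (n_markers, n_traits)
    freqs: AlleleFrequencies
    lam: float
    blend_beta: float
    source_ids: np.ndarray
    d_weights: str = "identity"

    def __post_init__(self):
        self.effects = np.atleast_2d(np.asarray(self.effects, dtype=float))
        if self.effects.shape[0] == 1 and self.freqs.p.size > 1:
            self.effects = self.effects.T
        self.source_ids = np.asarray(self.source_ids, dtype=np.int64)
        if self.effects.shape[0] != self.freqs.p.size:
            raise ValueError("marker count of effects does not match the panel")

    @property
    def n_markers(self) -> int:
        return self.effects.shape[0]

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]


def select_backsolve_subset(gebv_ids, n: int, seed: int) -> np.ndarray:
    """Uniform random sample of ``n`` ids without replacement (sorted,
    deterministic given the seed; ``n`` equal to the set size returns all)."""
    gebv_ids = np.sort(np.asarray(gebv_ids, dtype=np.int64))
    if n > gebv_ids.size:
        raise ValueError(f"requested subset of {n} from only {gebv_ids.size} animals")
    if n == gebv_ids.size:
        return gebv_ids
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(gebv_ids, size=n, replace=False))


def backsolve_snp_effects(
    Z_subset: np.ndarray,
    gebv_subset: BreedingValues | np.ndarray,
    freqs: AlleleFrequencies,
    blend_beta: float = 0.05,
    subset_ids=None,
) -> SnpEffects:
    """u = lambda Z' G^-1 a for the given subset of genotyped animals.

    ``Z_subset`` rows must align with ``gebv_subset``. G is ZZ'/k blended by
    ``blend_beta`` toward the identity; with ``blend_beta`` 0 and a full-rank
    subset, Z u reproduces the subset's breeding values exactly.
    """
    if isinstance(gebv_subset, BreedingValues):
        a_hat = gebv_subset.values
        subset_ids = gebv_subset.ids
    else:
        a_hat = np.atleast_2d(np.asarray(gebv_subset, dtype=float))
        if a_hat.shape[0] != Z_subset.shape[0]:
            a_hat = a_hat.T
        subset_ids = np.arange(Z_subset.shape[0]) if subset_ids is None else subset_ids
    if a_hat.shape[0] != Z_subset.shape[0]:
        raise ValueError("rows of Z_subset do not align with the breeding values")
    G = build_G(Z_subset, freqs, subset_ids, blend_beta, A22=None)
    try:
        Ginv = invert_dense_psd(G.matrix)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"subset G not invertible after blending (beta={blend_beta}): {e}")
    lam = 1.0 / G.k
    u_hat = lam * (Z_subset.T @ (Ginv @ a_hat))
    return SnpEffects(u_hat, freqs, lam, blend_beta, subset_ids)
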