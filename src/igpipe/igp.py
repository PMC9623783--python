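"""Indirect genomic prediction and genetic-base adjustment.

A target animal outside the evaluation receives IGP = Z u: its centered gene
contents times the backsolved marker effects. Because the marker effects are
expressed against the backsolving set's genetic base, IGP and GEBV can sit on
different bases; ``adjust_genetic_base`` aligns them either by the mean
GEBV - IGP difference on a reference set or by applying the validation
regression b0 + b1 * IGP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress

from .backsolve import SnpEffects
from .solver import BreedingValues

__all__ = ["IgpResult", "predict_igp", "adjust_genetic_base"]


@dataclass
class IgpResult:
    """Indirect predictions per target animal and trait."""

    ids: np.ndarray
    values: np.ndarray  # (n_targets, n_traits)
    adjustment: np.ndarray = field(default=None)
    provenance: str = ""

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.ids.size:
            self.values = self.values.T
        if self.adjustment is None:
            self.adjustment = np.zeros(self.values.shape[1])

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def as_breeding_values(self) -> BreedingValues:
        return BreedingValues(self.ids, self.values, source="igp")


def predict_igp(Z_targets: np.ndarray, effects: SnpEffects, target_ids=None) -> IgpResult:
    """IGP = Z u for target animals (rows of ``Z_targets``).

    ``Z_targets`` must be centered with the same allele frequencies the
    effects were backsolved with; missing genotypes, centered-imputed to
    zero, contribute nothing.
    """
    Z_targets = np.atleast_2d(np.asarray(Z_targets, dtype=float))
    if Z_targets.shape[1] != effects.n_markers:
        raise ValueError(
            f"marker panel mismatch: targets have {Z_targets.shape[1]} markers, effects {effects.n_markers}"
        )
    if target_ids is None:
        target_ids = np.arange(Z_targets.shape[0])
    values = Z_targets @ effects.effects
    return IgpResult(target_ids, values, provenance=f"backsolved from {effects.source_ids.size} animals")


def adjust_genetic_base(
    igp: IgpResult,
    reference_gebv: BreedingValues,
    reference_igp: IgpResult | None = None,
    mode: str = "mean_difference",
) -> IgpResult:
    """Shift IGP onto the GEBV genetic base.

    The reference set is the intersection of ``reference_gebv`` ids with
    ``reference_igp`` (default: the ``igp`` result itself). ``mean_difference``
    adds mean(GEBV) - mean(IGP) per trait; ``intercept`` regresses GEBV on IGP
    on the reference set and maps every target through b0 + b1 * IGP.
    """
    reference_igp = reference_igp or igp
    common = np.intersect1d(reference_igp.ids, reference_gebv.ids)
    if common.size == 0:
        raise ValueError("empty reference set: no ids with both GEBV and IGP")
    ref_idx = {a: i for i, a in enumerate(reference_igp.ids)}
    ref_rows = np.array([ref_idx[a] for a in common])
    g = reference_gebv.for_ids(common)
    v = reference_igp.values[ref_rows]
    if mode == "mean_difference":
        delta = g.mean(axis=0) - v.mean(axis=0)
        new_vals = igp.values + delta
        adj = igp.adjustment + delta
    elif mode == "intercept":
        new_vals = np.empty_like(igp.values)
        adj = np.empty(igp.n_traits)
        for tdx in range(igp.n_traits):
            fit = linregress(v[:, tdx], g[:, tdx])
            new_vals[:, tdx] = fit.intercept + fit.slope * igp.values[:, tdx]
            adj[tdx] = fit.intercept
    else:
        raise ValueError(f"unknown adjustment mode {mode!r}")
    return IgpResult(igp.ids, new_vals, adjustment=adj, provenance=igp.provenance + f" | base:{mode}")
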