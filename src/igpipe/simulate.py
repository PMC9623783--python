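"""Synthetic livestock population generator.

Emulates the data structure a large dairy genomic evaluation runs on: a
multi-generation pedigree under truncation selection on true breeding values
(creating a genetic trend), gene-dropped biallelic SNP genotypes without
linkage, multi-trait phenotypes from a repeatability animal model recorded on
females, and the three-way split of genotyped animals (direct GEBV /
indirect prediction / nongenotyped).

True breeding values are the sum of an infinitesimal marker-linked part (a
fraction ``marker_variance_fraction`` of the additive variance is carried by
small normal effects on every marker, so genomic relationships are
informative about the truth) and a polygenic part following the pedigree
recursion tbv = (tbv_s + tbv_d)/2 + Mendelian deviation. Markers are grouped
into ``n_linkage_blocks`` haplotype blocks that segregate as units (complete
linkage within a block, free recombination between blocks), emulating the
finite number of independent chromosome segments a real genome transmits;
``n_linkage_blocks=None`` gives fully independent markers.

All randomness derives from ``SimulationConfig.seed`` through independent
child streams per stage, so identical configurations reproduce bit-identical
populations regardless of which stages are run.

Scale conventions: each trait has phenotypic variance 1, so the additive
variance equals the heritability and all effects are in phenotypic-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .population import (
    MISSING_CODE,
    AnimalPartition,
    GenotypeMatrix,
    Pedigree,
    PhenotypeRecords,
    TrueValues,
)
from .solver import VarianceComponents

__all__ = [
    "SimulationConfig",
    "SimulatedData",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "partition_animals",
    "simulate",
    "selection_intensity_factor",
    "expected_response_per_generation",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic population.

    Defaults describe a desk-scale breeding population: five discrete
    generations from 500 founders with truncation selection of the best 40%
    of each sex on a single trait (h2 = 0.3, repeatability 0.45), 85% of
    animals genotyped for 1,000 unlinked markers carrying 80% of the additive
    variance, and half of the females phenotyped with one to three repeated
    records in recording-year contemporary groups.
    """

    n_founders: int = 500
    n_generations: int = 5
    offspring_per_dam: int = 5
    n_markers: int = 1000
    n_linkage_blocks: int | None = 200
    founder_haplotypes: int | None = 20
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 1
    heritabilities: tuple[float, ...] = (0.3,)
    genetic_correlations: tuple | None = None
    repeatability: tuple[float, ...] = (0.45,)
    selection_intensity: float = 0.4
    selection_intensity_males: float | None = 0.1
    selection_weights: tuple[float, ...] = (1.0,)
    marker_variance_fraction: float = 0.8
    prop_genotyped: float = 0.85
    prop_phenotyped_females: float = 0.5
    start_year: int = 2000
    first_record_age: int = 2
    max_records: int = 3
    missing_rate: float = 0.0
    cg_effect_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        t = self.n_traits
        if len(self.heritabilities) != t or len(self.repeatability) != t or len(self.selection_weights) != t:
            raise ValueError("per-trait parameter lengths must equal n_traits")
        for h, r in zip(self.heritabilities, self.repeatability):
            if not 0.0 < h <= 1.0:
                raise ValueError("heritabilities must be in (0, 1]")
            if not h <= r <= 1.0:
                raise ValueError("repeatability must satisfy h2 <= r <= 1")
        lo, hi = self.founder_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("founder_maf_range must be within (0, 0.5]")
        if not 0.0 < self.selection_intensity <= 1.0:
            raise ValueError("selection_intensity must be in (0, 1]")
        if self.selection_intensity_males is not None and not 0.0 < self.selection_intensity_males <= 1.0:
            raise ValueError("selection_intensity_males must be in (0, 1]")
        if not 0.0 <= self.marker_variance_fraction <= 1.0:
            raise ValueError("marker_variance_fraction must be in [0, 1]")
        for name in ("prop_genotyped", "prop_phenotyped_females"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_linkage_blocks is not None and self.n_linkage_blocks < 1:
            raise ValueError("n_linkage_blocks must be positive (or None for no linkage)")
        if self.founder_haplotypes is not None and self.founder_haplotypes < 2:
            raise ValueError("founder_haplotypes must be >= 2 (or None for unrelated founder gametes)")
        R = self.corr_matrix()
        if np.linalg.eigvalsh(R)[0] < -1e-10:
            raise ValueError("genetic correlation matrix is not positive semi-definite")

    def corr_matrix(self) -> np.ndarray:
        if self.genetic_correlations is None:
            return np.eye(self.n_traits)
        R = np.asarray(self.genetic_correlations, dtype=float)
        if R.shape != (self.n_traits, self.n_traits) or not np.allclose(R, R.T):
            raise ValueError("genetic_correlations must be a symmetric n_traits x n_traits matrix")
        return R

    def variance_components(self) -> VarianceComponents:
        """True generating (co)variances on the phenotypic-SD-1 scale."""
        h = np.asarray(self.heritabilities)
        rep = np.asarray(self.repeatability)
        sd_a = np.sqrt(h)
        Sa = self.corr_matrix() * np.outer(sd_a, sd_a)
        Spe = np.diag(rep - h)
        Se = np.diag(1.0 - rep)
        return VarianceComponents(Sa, Se, Spe)

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(4)[stage])

    def _block_sizes(self) -> np.ndarray:
        """Marker counts per linkage block (contiguous, near-equal)."""
        m = self.n_markers
        b = m if self.n_linkage_blocks is None else min(self.n_linkage_blocks, m)
        if m == 0:
            return np.zeros(0, dtype=np.int64)
        sizes = np.full(b, m // b, dtype=np.int64)
        sizes[: m % b] += 1
        return sizes


@dataclass
class SimulatedData:
    """Bundle produced by :func:`simulate`."""

    config: SimulationConfig
    pedigree: Pedigree
    truth: TrueValues
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeRecords
    variance_components: VarianceComponents = field(init=False)

    def __post_init__(self):
        self.variance_components = self.config.variance_components()


def selection_intensity_factor(p: float) -> float:
    """Standardized selection differential i = phi(z)/p for truncation at
    proportion ``p`` selected."""
    if p >= 1.0:
        return 0.0
    z = norm.ppf(1.0 - p)
    return float(norm.pdf(z) / p)


def expected_response_per_generation(config: SimulationConfig, trait: int = 0) -> float:
    """Breeder's-equation response per generation for truncation selection
    directly on the true breeding value of a single trait: the sexes' mean
    standardized selection differential times sigma_a."""
    p_m = config.selection_intensity if config.selection_intensity_males is None else config.selection_intensity_males
    i = 0.5 * (selection_intensity_factor(config.selection_intensity) + selection_intensity_factor(p_m))
    sigma_a = float(np.sqrt(config.heritabilities[trait]))
    return i * sigma_a


def _founder_gametes(drop: np.random.Generator, config: SimulationConfig, n_founders: int, p: np.ndarray):
    """Two gametes per founder. With a finite ``founder_haplotypes`` pool,
    each linkage block samples its haplotypes from ``H`` ancestral block
    haplotypes (limited segment diversity, as in a population with small
    effective size); with ``None`` every gamete is an independent draw."""
    m = p.size
    a1 = np.zeros((n_founders, m), dtype=np.int8)
    a2 = np.zeros((n_founders, m), dtype=np.int8)
    if m == 0 or n_founders == 0:
        return a1, a2
    H = config.founder_haplotypes
    if H is None:
        a1[:] = drop.random((n_founders, m)) < p
        a2[:] = drop.random((n_founders, m)) < p
        return a1, a2
    bsz = config._block_sizes()
    stop = np.cumsum(bsz)
    for b in range(bsz.size):
        cols = slice(stop[b] - bsz[b], stop[b])
        pool = (drop.random((H, bsz[b])) < p[cols]).astype(np.int8)
        a1[:, cols] = pool[drop.integers(0, H, n_founders)]
        a2[:, cols] = pool[drop.integers(0, H, n_founders)]
    return a1, a2


def _generation_sizes(config: SimulationConfig) -> list[int]:
    p_m = config.selection_intensity if config.selection_intensity_males is None else config.selection_intensity_males
    sizes = [config.n_founders]
    for g in range(config.n_generations - 1):
        n_f = sizes[-1] // 2  # sexes alternate M,F starting at M
        n_dams = int(np.floor(config.selection_intensity * n_f))
        n_m = sizes[-1] - n_f
        n_sires = int(np.floor(p_m * n_m))
        if n_dams < 1 or n_sires < 1:
            raise ValueError(
                f"selection_intensity {config.selection_intensity} leaves no "
                f"{'dams' if n_dams < 1 else 'sires'} in generation {g}"
            )
        sizes.append(n_dams * config.offspring_per_dam)
    return sizes


class _Population:
    """Full internal state of one simulated population (pedigree, alleles,
    true values); built once, viewed by the public stage functions."""

    def __init__(self, config: SimulationConfig):
        rng = config._rng(0)  # selection, polygenic TBV, PE
        drop = config._rng(1)  # marker frequencies, effects, gene drop
        t = config.n_traits
        m = config.n_markers
        Sa = config.variance_components().additive
        fm = config.marker_variance_fraction if m else 0.0
        La_poly = np.linalg.cholesky((1.0 - fm) * Sa + 1e-12 * np.eye(t))
        weights = np.asarray(config.selection_weights, dtype=float)

        lo, hi = config.founder_maf_range
        self.p_founder = drop.uniform(lo, hi, m)
        k_f = float(2.0 * np.sum(self.p_founder * (1.0 - self.p_founder)))
        if m and fm > 0.0:
            La_mark = np.linalg.cholesky(fm * Sa + 1e-12 * np.eye(t))
            self.alpha = drop.standard_normal((m, t)) @ La_mark.T / np.sqrt(k_f)
        else:
            self.alpha = np.zeros((m, t))

        sizes = _generation_sizes(config)
        n = int(np.sum(sizes))
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        self.birth_year = np.empty(n, dtype=np.int64)
        self.sex = np.empty(n, dtype="U1")
        self.a1 = np.zeros((n, m), dtype=np.int8)
        self.a2 = np.zeros((n, m), dtype=np.int8)
        self.tbv = np.zeros((n, t))
        poly = np.zeros((n, t))
        A = np.zeros((n, n))

        def marker_bv(rows):
            codes = (self.a1[rows] + self.a2[rows]).astype(float)
            return (codes - 2.0 * self.p_founder) @ self.alpha

        n0 = config.n_founders
        self.sex[:n0] = np.where(np.arange(n0) % 2 == 0, "M", "F")
        self.birth_year[:n0] = config.start_year
        self.a1[:n0], self.a2[:n0] = _founder_gametes(drop, config, n0, self.p_founder)
        poly[:n0] = rng.standard_normal((n0, t)) @ La_poly.T
        self.tbv[:n0] = marker_bv(np.arange(n0)) + poly[:n0]
        A[:n0, :n0] = np.eye(n0)

        start = 0
        for g in range(1, config.n_generations):
            gen = np.arange(start, start + sizes[g - 1])
            start += sizes[g - 1]
            males = gen[self.sex[gen] == "M"]
            females = gen[self.sex[gen] == "F"]
            p_m = config.selection_intensity if config.selection_intensity_males is None else config.selection_intensity_males
            n_sires = int(np.floor(p_m * males.size))
            n_dams = int(np.floor(config.selection_intensity * females.size))
            if weights.any():
                index = self.tbv[:, : weights.size] @ weights
                sires = males[np.argsort(-index[males], kind="stable")[:n_sires]]
                dams = females[np.argsort(-index[females], kind="stable")[:n_dams]]
            else:
                sires = rng.permutation(males)[:n_sires]
                dams = rng.permutation(females)[:n_dams]

            n_off = n_dams * config.offspring_per_dam
            off = np.arange(start, start + n_off)
            self.dam_idx[off] = np.repeat(dams, config.offspring_per_dam)
            self.sire_idx[off] = sires[rng.integers(0, sires.size, n_off)]
            self.birth_year[off] = config.start_year + g
            self.sex[off] = np.where(np.arange(n_off) % 2 == 0, "M", "F")

            if m:
                s, d = self.sire_idx[off], self.dam_idx[off]
                bsz = config._block_sizes()
                pick = np.repeat(drop.integers(0, 2, (n_off, bsz.size), dtype=np.int8), bsz, axis=1)
                self.a1[off] = np.where(pick == 0, self.a1[s], self.a2[s])
                pick = np.repeat(drop.integers(0, 2, (n_off, bsz.size), dtype=np.int8), bsz, axis=1)
                self.a2[off] = np.where(pick == 0, self.a1[d], self.a2[d])

            # grow the tabular A blockwise: the cross block against all
            # earlier animals, then the sibling block from the parents'
            # mutual relationships (parents always precede the block)
            s, d = self.sire_idx[off], self.dam_idx[off]
            prev = off[0]
            A[off, :prev] = 0.5 * (A[s, :prev] + A[d, :prev])
            A[:prev, off] = A[off, :prev].T
            block = 0.25 * (
                A[np.ix_(s, s)] + A[np.ix_(s, d)] + A[np.ix_(d, s)] + A[np.ix_(d, d)]
            )
            A[np.ix_(off, off)] = block
            A[off, off] = 1.0 + 0.5 * A[s, d]

            Fbar = 0.5 * (A[s, s] - 1.0 + A[d, d] - 1.0)
            scale = np.sqrt(0.5 * (1.0 - Fbar))
            mend = rng.standard_normal((n_off, t)) @ La_poly.T * scale[:, None]
            poly[off] = 0.5 * (poly[s] + poly[d]) + mend
            self.tbv[off] = marker_bv(off) + poly[off]

        self.ids = np.arange(1, n + 1, dtype=np.int64)
        sire = np.where(self.sire_idx >= 0, self.ids[np.maximum(self.sire_idx, 0)], 0)
        dam = np.where(self.dam_idx >= 0, self.ids[np.maximum(self.dam_idx, 0)], 0)
        self.pedigree = Pedigree(self.ids, sire, dam, self.birth_year, self.sex)

        Spe = config.variance_components().permanent_env
        self.pe = rng.standard_normal((n, t)) @ np.sqrt(np.diag(np.diag(Spe)))
        self.truth = TrueValues(self.ids, self.tbv, self.pe)

    def matches(self, ped: Pedigree) -> bool:
        return (
            ped.n_animals == self.pedigree.n_animals
            and np.array_equal(ped.ids, self.pedigree.ids)
            and np.array_equal(ped.sire_idx, self.pedigree.sire_idx)
            and np.array_equal(ped.dam_idx, self.pedigree.dam_idx)
        )


def simulate_pedigree(config: SimulationConfig) -> tuple[Pedigree, TrueValues]:
    """Build a multi-generation pedigree with true breeding values.

    Parents of generation g+1 are the top ``selection_intensity`` fraction of
    each sex of generation g, ranked on the selection-weighted true breeding
    value (all-zero weights give random selection). TBVs are the sum of
    marker-linked effects (gene-dropped) and a polygenic part following the
    infinitesimal recursion  tbv = (tbv_s + tbv_d)/2 + m  with Mendelian
    sampling variance 0.5 (1 - (F_s + F_d)/2) Sigma_a; inbreeding is tracked
    exactly by growing the tabular relationship matrix. Offspring sexes
    alternate deterministically so both sexes exist in every generation.
    """
    pop = _Population(config)
    return pop.pedigree, pop.truth


def _generation_levels(ped: Pedigree) -> np.ndarray:
    level = np.zeros(ped.n_animals, dtype=np.int64)
    for i in range(ped.n_animals):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        lp = 0
        if s >= 0:
            lp = level[s] + 1
        if d >= 0:
            lp = max(lp, level[d] + 1)
        level[i] = lp
    return level


def _standalone_drop(ped: Pedigree, config: SimulationConfig):
    """Gene-drop on an arbitrary pedigree (used when ``ped`` was not produced
    by this config; marker effects then play no role in the pedigree)."""
    rng = config._rng(1)
    n, m = ped.n_animals, config.n_markers
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, m)
    a1 = np.zeros((n, m), dtype=np.int8)
    a2 = np.zeros((n, m), dtype=np.int8)
    levels = _generation_levels(ped)
    for lev in range(levels.max() + 1) if n else range(0):
        grp = np.flatnonzero(levels == lev)
        founders = grp[ped.sire_idx[grp] < 0]
        if founders.size and m:
            a1[founders], a2[founders] = _founder_gametes(rng, config, founders.size, p)
        kids = grp[ped.sire_idx[grp] >= 0]
        if kids.size and m:
            s, d = ped.sire_idx[kids], ped.dam_idx[kids]
            bsz = config._block_sizes()
            pick = np.repeat(rng.integers(0, 2, (kids.size, bsz.size), dtype=np.int8), bsz, axis=1)
            a1[kids] = np.where(pick == 0, a1[s], a2[s])
            pick = np.repeat(rng.integers(0, 2, (kids.size, bsz.size), dtype=np.int8), bsz, axis=1)
            a2[kids] = np.where(pick == 0, a1[d], a2[d])
    return a1, a2


def _genotypes_from_alleles(ped: Pedigree, a1, a2, config: SimulationConfig) -> GenotypeMatrix:
    rng = config._rng(3)  # genotyped subset and missing-call injection
    codes = (a1 + a2).astype(np.int8)
    keep = rng.random(ped.n_animals) < config.prop_genotyped
    if not keep.any():
        keep[:] = True  # degenerate config: keep everyone rather than nobody
    codes = codes[keep]
    if config.missing_rate > 0.0 and config.n_markers:
        miss = rng.random(codes.shape) < config.missing_rate
        codes[miss] = MISSING_CODE
    return GenotypeMatrix(ped.ids[keep], codes)


def simulate_genotypes(ped: Pedigree, config: SimulationConfig) -> GenotypeMatrix:
    """Gene-dropped biallelic genotypes for a random ``prop_genotyped``
    fraction of the pedigree.

    Founder alleles are Bernoulli draws at per-marker frequencies uniform on
    ``founder_maf_range``; descendants inherit one allele per parent per
    marker, independently across markers (no linkage). For the pedigree this
    config itself generates, the returned genotypes are exactly the alleles
    dropped during pedigree construction (they underlie the marker-linked
    TBV); for any other pedigree a standalone gene drop is performed.
    Missing calls are injected at ``missing_rate``.
    """
    pop = _Population(config)
    if pop.matches(ped):
        a1, a2 = pop.a1, pop.a2
    else:
        a1, a2 = _standalone_drop(ped, config)
    return _genotypes_from_alleles(ped, a1, a2, config)


def simulate_phenotypes(ped: Pedigree, truth: TrueValues, config: SimulationConfig) -> PhenotypeRecords:
    """Repeatability-model phenotypes on females.

    y = contemporary-group effect + TBV + permanent-environment deviation +
    record-specific residual, per trait. The contemporary group is the
    recording year (birth year + ``first_record_age`` + record number - 1),
    so cows of different cohorts are compared in the same group through their
    repeated records. Group effects are i.i.d. normal with SD
    ``cg_effect_sd``. Each phenotyped female (probability
    ``prop_phenotyped_females``) receives 1 to ``max_records`` records.
    """
    rng = config._rng(2)
    t = config.n_traits
    se_sd = np.sqrt(np.diag(config.variance_components().residual))
    is_f = ped.sex == "F"
    pheno = is_f & (rng.random(ped.n_animals) < config.prop_phenotyped_females)
    animals = np.flatnonzero(pheno)
    if animals.size == 0:
        return PhenotypeRecords(pd.DataFrame(columns=PhenotypeRecords.COLUMNS))
    n_rec = rng.integers(1, config.max_records + 1, animals.size)
    rec_animal = np.repeat(animals, n_rec)
    rec_no = np.concatenate([np.arange(1, k + 1) for k in n_rec])

    rec_year = ped.birth_year[rec_animal] + config.first_record_age + rec_no - 1
    levels = np.char.add("Y", rec_year.astype(str))
    uniq = np.unique(levels)
    cg_effects = {lv: e for lv, e in zip(uniq, rng.normal(0.0, config.cg_effect_sd, (uniq.size, t)))}
    cg = np.array([cg_effects[lv] for lv in levels])

    resid = rng.standard_normal((rec_animal.size, t)) * se_sd
    y = cg + truth.tbv[rec_animal] + truth.pe[rec_animal] + resid

    frame = pd.DataFrame(
        {
            "id": np.repeat(ped.ids[rec_animal], t),
            "trait": np.tile(np.arange(t), rec_animal.size),
            "value": y.ravel(),
            "fixed_level": np.repeat(levels, t),
            "record_no": np.repeat(rec_no, t),
        }
    )
    return PhenotypeRecords(frame)


def partition_animals(
    ped: Pedigree, phen: PhenotypeRecords, geno: GenotypeMatrix, cutoff_year: int
) -> AnimalPartition:
    """Split animals into direct-GEBV, indirect-prediction and nongenotyped sets.

    Genotyped animals with phenotypes or progeny go to the GEBV set; genotyped
    animals with neither, born on/after ``cutoff_year``, are the indirect-
    prediction targets. Genotyped animals with neither that are older than the
    cutoff stay in the GEBV set (they would remain in the evaluation).
    """
    pos = ped.positions(geno.ids)  # raises naming the id if absent
    has_prog = ped.has_progeny()[pos]
    has_phen = np.isin(geno.ids, phen.animal_ids)
    young = ped.birth_year[pos] >= cutoff_year
    igp = ~has_prog & ~has_phen & young
    gebv_ids = geno.ids[~igp]
    igp_ids = geno.ids[igp]
    nong = np.setdiff1d(ped.ids, geno.ids)
    return AnimalPartition(gebv_ids, igp_ids, nong, cutoff_year)


def simulate(config: SimulationConfig) -> SimulatedData:
    """Run all generator stages once and bundle the results."""
    pop = _Population(config)
    geno = _genotypes_from_alleles(pop.pedigree, pop.a1, pop.a2, config)
    phen = simulate_phenotypes(pop.pedigree, pop.truth, config)
    return SimulatedData(config, pop.pedigree, pop.truth, geno, phen)
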