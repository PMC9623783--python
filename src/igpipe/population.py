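"""In-memory containers for pedigreed populations.

The containers here are deliberately thin wrappers around numpy arrays and
pandas frames: a :class:`Pedigree` (animal, sire, dam, birth year, sex), a
:class:`GenotypeMatrix` of 0/1/2 SNP allele counts, long-format
:class:`PhenotypeRecords` with repeated records, simulated ground truth
(:class:`TrueValues`), and the three-way :class:`AnimalPartition` of genotyped
animals used throughout the indirect-prediction workflow.

Animals are renumbered internally to consecutive 0-based positions sorted
parents-before-offspring; original identifiers are preserved for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "GenotypeMatrix",
    "PhenotypeRecords",
    "TrueValues",
    "AnimalPartition",
    "MISSING_CODE",
]

#: internal sentinel for a missing genotype call (files use the digit 5)
MISSING_CODE = -1


class Pedigree:
    """A pedigree sorted parents-before-offspring.

    Parameters
    ----------
    ids
        Original animal identifiers (positive integers, unique).
    sire, dam
        Parent identifiers; ``0`` denotes an unknown parent.
    birth_year
        Integer year of birth per animal.
    sex
        Per-animal sex, ``"M"`` or ``"F"``.

    The constructor validates identifiers, topologically sorts animals so
    every parent precedes its offspring, and builds 0-based ``sire_idx`` /
    ``dam_idx`` arrays (``-1`` = unknown) used by all relationship code.
    """

    def __init__(self, ids, sire, dam, birth_year, sex):
        ids = np.asarray(ids, dtype=np.int64)
        sire = np.asarray(sire, dtype=np.int64)
        dam = np.asarray(dam, dtype=np.int64)
        birth_year = np.asarray(birth_year, dtype=np.int64)
        sex = np.asarray(sex, dtype="U1")
        n = ids.size
        if not (sire.size == dam.size == birth_year.size == sex.size == n):
            raise ValueError("pedigree columns have unequal lengths")
        if n and ids.min() <= 0:
            raise ValueError("animal ids must be positive integers")
        if np.unique(ids).size != n:
            raise ValueError("duplicate animal ids in pedigree")
        bad_sex = ~np.isin(sex, ["M", "F"])
        if bad_sex.any():
            raise ValueError(f"sex must be 'M' or 'F' (got {sex[bad_sex][0]!r})")
        known = np.concatenate([sire[sire != 0], dam[dam != 0]])
        missing = np.setdiff1d(known, ids)
        if missing.size:
            raise ValueError(f"parent id {missing[0]} not in pedigree")

        order = self._topological_order(ids, sire, dam, birth_year)
        self.ids = ids[order]
        self.birth_year = birth_year[order]
        self.sex = sex[order]
        self._index = pd.Index(self.ids)
        self.sire_idx = self._parent_positions(sire[order])
        self.dam_idx = self._parent_positions(dam[order])
        own = np.arange(n)
        if ((self.sire_idx >= own) | (self.dam_idx >= own)).any():
            raise ValueError("pedigree could not be sorted parents-first")

    @staticmethod
    def _topological_order(ids, sire, dam, birth_year):
        n = ids.size
        pos = pd.Index(ids)
        s = np.where(sire != 0, pos.get_indexer(sire), -1)
        d = np.where(dam != 0, pos.get_indexer(dam), -1)
        # already sorted? (the common case for simulator output)
        own = np.arange(n)
        if ((s < own) & (d < own)).all():
            return own
        # Kahn's algorithm, preferring earlier birth years then smaller ids
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=np.int64)
        for i in range(n):
            for p in (s[i], d[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        import heapq

        heap = [(birth_year[i], ids[i], i) for i in range(n) if indeg[i] == 0]
        heapq.heapify(heap)
        order = []
        while heap:
            _, _, i = heapq.heappop(heap)
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(heap, (birth_year[c], ids[c], c))
        if len(order) != n:
            cyc = ids[indeg > 0]
            raise ValueError(f"pedigree contains an ancestry cycle involving ids {cyc[:5].tolist()}")
        return np.asarray(order)

    def _parent_positions(self, parent_ids):
        idx = np.full(parent_ids.size, -1, dtype=np.int64)
        known = parent_ids != 0
        idx[known] = self._index.get_indexer(parent_ids[known])
        return idx

    @property
    def n_animals(self) -> int:
        return self.ids.size

    def positions(self, ids) -> np.ndarray:
        """0-based internal positions of ``ids``; raises on unknown id."""
        pos = self._index.get_indexer(np.asarray(ids, dtype=np.int64))
        if (pos < 0).any():
            bad = np.asarray(ids)[pos < 0][0]
            raise KeyError(f"animal id {bad} not in pedigree")
        return pos

    def __contains__(self, animal_id) -> bool:
        return int(animal_id) in self._index

    def has_progeny(self) -> np.ndarray:
        """Boolean array: does animal i appear as a sire or dam?"""
        out = np.zeros(self.n_animals, dtype=bool)
        out[self.sire_idx[self.sire_idx >= 0]] = True
        out[self.dam_idx[self.dam_idx >= 0]] = True
        return out

    def to_frame(self) -> pd.DataFrame:
        sire = np.where(self.sire_idx >= 0, self.ids[np.maximum(self.sire_idx, 0)], 0)
        dam = np.where(self.dam_idx >= 0, self.ids[np.maximum(self.dam_idx, 0)], 0)
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": sire,
                "dam": dam,
                "birth_year": self.birth_year,
                "sex": self.sex,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            df["id"].to_numpy(),
            df["sire"].to_numpy(),
            df["dam"].to_numpy(),
            df["birth_year"].to_numpy(),
            df["sex"].to_numpy(),
        )


class GenotypeMatrix:
    """SNP allele counts (0/1/2) for a set of genotyped animals.

    ``codes`` is an ``int8`` matrix of animals x markers with ``-1`` marking a
    missing call. Codes outside {0, 1, 2, missing} are rejected.
    """

    def __init__(self, ids, codes, marker_ids=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        codes = np.asarray(codes)
        if codes.ndim != 2 or codes.shape[0] != self.ids.size:
            raise ValueError("codes must be (n_animals, n_markers)")
        valid = np.isin(codes, [0, 1, 2, MISSING_CODE])
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(f"invalid genotype code {codes[i, j]} at animal {self.ids[i]}, marker {j}")
        self.codes = codes.astype(np.int8)
        if marker_ids is None:
            marker_ids = np.array([f"M{j + 1}" for j in range(codes.shape[1])])
        self.marker_ids = np.asarray(marker_ids)
        if self.marker_ids.size != codes.shape[1]:
            raise ValueError("marker_ids length mismatch")
        self._index = pd.Index(self.ids)

    @property
    def n_animals(self) -> int:
        return self.ids.size

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def rows(self, ids) -> np.ndarray:
        """Row positions for ``ids`` (error on a non-genotyped id)."""
        pos = self._index.get_indexer(np.asarray(ids, dtype=np.int64))
        if (pos < 0).any():
            bad = np.asarray(ids)[pos < 0][0]
            raise KeyError(f"animal id {bad} is not genotyped")
        return pos

    def subset(self, ids) -> "GenotypeMatrix":
        return GenotypeMatrix(ids, self.codes[self.rows(ids)], self.marker_ids)


class PhenotypeRecords:
    """Long-format phenotype records: one row per animal x trait x record.

    Columns: ``id``, ``trait`` (0-based index), ``value``, ``fixed_level``
    (contemporary-group label), ``record_no`` (1-based, distinguishes repeated
    records of the same animal).
    """

    COLUMNS = ["id", "trait", "value", "fixed_level", "record_no"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"phenotype frame missing columns {missing}")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def animal_ids(self) -> np.ndarray:
        return np.unique(self.frame["id"].to_numpy())

    def n_traits(self) -> int:
        return int(self.frame["trait"].max()) + 1 if len(self.frame) else 0

    def wide(self, n_traits: int) -> pd.DataFrame:
        """Pivot to one row per (id, fixed_level, record_no) with trait columns.

        Traits unobserved for a record come out as NaN.
        """
        if not len(self.frame):
            cols = {f"t{t}": [] for t in range(n_traits)}
            return pd.DataFrame({"id": [], "fixed_level": [], "record_no": [], **cols})
        wide = self.frame.pivot_table(
            index=["id", "fixed_level", "record_no"],
            columns="trait",
            values="value",
            aggfunc="first",
        )
        wide = wide.reindex(columns=range(n_traits))
        wide.columns = [f"t{t}" for t in range(n_traits)]
        return wide.reset_index()


@dataclass
class TrueValues:
    """Simulated ground truth: true breeding values and permanent-environment
    deviations per animal (rows follow pedigree order)."""

    ids: np.ndarray
    tbv: np.ndarray  # (n_animals, n_traits)
    pe: np.ndarray  # (n_animals, n_traits)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.tbv = np.atleast_2d(np.asarray(self.tbv, dtype=float))
        self.pe = np.atleast_2d(np.asarray(self.pe, dtype=float))

    @property
    def n_traits(self) -> int:
        return self.tbv.shape[1]


@dataclass
class AnimalPartition:
    """Three-way split of animals for the indirect-prediction workflow.

    ``gebv_ids``: genotyped animals with phenotypes or progeny (they enter the
    reduced single-step evaluation directly); ``igp_ids``: genotyped animals
    with neither, born on/after ``cutoff_year`` (they receive indirect
    predictions); ``nongenotyped_ids``: everyone else in the pedigree.
    """

    gebv_ids: np.ndarray
    igp_ids: np.ndarray
    nongenotyped_ids: np.ndarray
    cutoff_year: int
    shares: dict = field(init=False)

    def __post_init__(self):
        self.gebv_ids = np.asarray(self.gebv_ids, dtype=np.int64)
        self.igp_ids = np.asarray(self.igp_ids, dtype=np.int64)
        self.nongenotyped_ids = np.asarray(self.nongenotyped_ids, dtype=np.int64)
        if np.intersect1d(self.gebv_ids, self.igp_ids).size:
            raise ValueError("GEBV and IGP sets overlap")
        self.shares = {
            "gebv": share_percent(self.gebv_ids.size, self.n_genotyped),
            "igp": share_percent(self.igp_ids.size, self.n_genotyped),
        }

    @property
    def n_genotyped(self) -> int:
        return self.gebv_ids.size + self.igp_ids.size


def share_percent(count: int, total: int) -> int:
    """Share of ``count`` in ``total`` as a percentage rounded to nearest int."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * count / total))
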