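"""File formats: pedigree/phenotype CSV, fixed-width genotype text, reports.

The genotype dialect follows the BLUPF90 family convention: one animal per
line, its id, whitespace, then a contiguous digit string of per-marker codes
(0/1/2, with 5 marking a missing call). Pedigrees are CSV with 0 for an
unknown parent. Readers validate as they parse and report offending line
numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population import MISSING_CODE, GenotypeMatrix, Pedigree, PhenotypeRecords, TrueValues

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_true_values",
    "write_snp_effects",
    "write_manifest",
    "read_config",
]

_PED_COLUMNS = ["id", "sire", "dam", "birth_year", "sex"]


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _PED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pedigree file missing columns {missing}")
    return Pedigree.from_frame(df)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    codes = geno.codes.astype(np.int8).copy()
    codes[codes == MISSING_CODE] = 5
    width = max((len(str(i)) for i in geno.ids), default=1)
    with open(path, "w") as fh:
        for animal, row in zip(geno.ids, codes):
            fh.write(f"{animal:<{width}} {''.join(map(str, row))}\n")


def read_genotypes(path) -> GenotypeMatrix:
    ids, rows = [], []
    n_markers = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'id genotypes', got {len(parts)} fields")
            animal, digits = parts
            if n_markers is None:
                n_markers = len(digits)
            elif len(digits) != n_markers:
                raise ValueError(
                    f"{path}:{ln}: genotype string length {len(digits)} differs from {n_markers}"
                )
            row = np.frombuffer(digits.encode(), dtype=np.uint8) - ord("0")
            bad = ~np.isin(row, [0, 1, 2, 5])
            if bad.any():
                raise ValueError(f"{path}:{ln}: invalid genotype code {row[bad][0]}")
            row = row.astype(np.int8)
            row[row == 5] = MISSING_CODE
            ids.append(int(animal))
            rows.append(row)
    return GenotypeMatrix(np.array(ids, dtype=np.int64), np.array(rows, dtype=np.int8))


def write_phenotypes(phen: PhenotypeRecords, path) -> None:
    phen.frame.to_csv(path, index=False)


def read_phenotypes(path, ped: Pedigree | None = None) -> PhenotypeRecords:
    df = pd.read_csv(path, float_precision="round_trip")
    phen = PhenotypeRecords(df)
    if ped is not None:
        unknown = np.setdiff1d(phen.animal_ids, ped.ids)
        if unknown.size:
            raise ValueError(f"{path}: phenotyped animal {unknown[0]} not in pedigree")
    return phen


def write_true_values(truth: TrueValues, path) -> None:
    t = truth.n_traits
    df = pd.DataFrame({"id": truth.ids})
    for j in range(t):
        df[f"tbv_t{j}"] = truth.tbv[:, j]
    for j in range(t):
        df[f"pe_t{j}"] = truth.pe[:, j]
    df.to_csv(path, index=False)


def write_snp_effects(effects, path) -> None:
    """CSV with header marker,trait,effect,freq (long format)."""
    m, t = effects.effects.shape
    df = pd.DataFrame(
        {
            "marker": np.repeat(np.arange(1, m + 1), t),
            "trait": np.tile(np.arange(t), m),
            "effect": effects.effects.ravel(),
            "freq": np.repeat(effects.freqs.p, t),
        }
    )
    df.to_csv(path, index=False)


def write_manifest(manifest: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(manifest, indent=2, default=_default) + "\n")


def read_config(path) -> dict:
    """Structured pipeline configuration from YAML."""
    with open(path) as fh:
        return yaml.safe_load(fh)
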