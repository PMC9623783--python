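"""Simulate the study population and write its files.

Generates the dairy-like population (pedigree under directional selection,
gene-dropped genotypes, repeated-record phenotypes on cows), partitions the
genotyped animals into the direct-GEBV and indirect-prediction classes, and
writes everything under results/data/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CUTOFF_YEAR, RESULTS, STUDY_CONFIG

from igpipe import io as igio
from igpipe.simulate import partition_animals, simulate


def main():
    out = RESULTS / "data"
    out.mkdir(parents=True, exist_ok=True)
    data = simulate(STUDY_CONFIG)
    part = partition_animals(data.pedigree, data.phenotypes, data.genotypes, CUTOFF_YEAR)

    igio.write_pedigree(data.pedigree, out / "pedigree.csv")
    igio.write_genotypes(data.genotypes, out / "genotypes.txt")
    igio.write_phenotypes(data.phenotypes, out / "phenotypes.csv")
    igio.write_true_values(data.truth, out / "true_values.csv")
    igio.write_manifest(
        {
            "config": {k: v for k, v in STUDY_CONFIG.__dict__.items()},
            "n_animals": data.pedigree.n_animals,
            "n_genotyped": data.genotypes.n_animals,
            "n_records": data.phenotypes.n_records,
            "partition": {
                "cutoff_year": CUTOFF_YEAR,
                "n_gebv": part.gebv_ids.size,
                "n_igp": part.igp_ids.size,
                "shares_pct": part.shares,
            },
        },
        out / "manifest.json",
    )
    print(
        f"simulated {data.pedigree.n_animals} animals, {data.genotypes.n_animals} genotyped "
        f"({part.gebv_ids.size} GEBV / {part.igp_ids.size} IGP, "
        f"{part.shares['gebv']}%/{part.shares['igp']}%), "
        f"{data.phenotypes.n_records} phenotype records -> {out}"
    )


if __name__ == "__main__":
    main()
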