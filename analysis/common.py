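"""Shared configuration for the numbered analysis scripts.

One dairy-like synthetic population is used throughout: 400 founders, five
generations, intense sire selection, a 2,000-marker panel organised in 200
haplotype blocks drawn from a 20-haplotype ancestral pool, h2 = 0.3 with
repeatability 0.45. The scripts write their tables under results/.
"""

from pathlib import Path

from igpipe.simulate import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY_CONFIG = SimulationConfig(
    n_founders=400,
    offspring_per_dam=7,
    n_generations=5,
    n_markers=2000,
    heritabilities=(0.3,),
    repeatability=(0.45,),
    seed=1,
)
CUTOFF_YEAR = STUDY_CONFIG.start_year + STUDY_CONFIG.n_generations - 1

TRAIT_PANEL_CONFIG = SimulationConfig(
    n_founders=250,
    offspring_per_dam=6,
    n_generations=5,
    n_markers=600,
    n_traits=3,
    heritabilities=(0.35, 0.3, 0.25),
    repeatability=(0.5, 0.45, 0.4),
    selection_weights=(1.0, 0.5, 0.0),
    genetic_correlations=((1.0, 0.3, 0.1), (0.3, 1.0, 0.2), (0.1, 0.2, 1.0)),
    seed=5,
)
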