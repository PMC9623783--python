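import numpy as np
import pytest

from igpipe.population import Pedigree
from igpipe.simulate import (
    SimulationConfig,
    expected_response_per_generation,
    partition_animals,
    simulate,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from igpipe.validation import genetic_trend


class TestSimulatePedigree:
    def test_single_generation_all_founders(self):
        cfg = SimulationConfig(n_founders=10, n_generations=1, n_markers=0)
        ped, truth = simulate_pedigree(cfg)
        assert ped.n_animals == 10
        assert (ped.sire_idx == -1).all() and (ped.dam_idx == -1).all()

    def test_no_selection_no_trend(self):
        cfg = SimulationConfig(
            n_founders=1000,
            n_generations=4,
            offspring_per_dam=5,
            selection_intensity=0.4,
            selection_intensity_males=0.4,
            selection_weights=(0.0,),
            n_markers=0,
            seed=31,
        )
        ped, truth = simulate_pedigree(cfg)
        sd = np.sqrt(cfg.heritabilities[0])
        trend = genetic_trend(truth.tbv, ped.birth_year, [sd])[0]
        assert abs(trend) < 0.06

    def test_trend_matches_breeders_equation(self):
        """Realized per-generation response within 25% of i * sigma_a over 10
        seeds, with truncation selection directly on TBV in both sexes."""
        cfg0 = SimulationConfig(
            n_founders=500,
            n_generations=5,
            offspring_per_dam=10,
            selection_intensity=0.2,
            selection_intensity_males=0.2,
            n_markers=0,
        )
        expected = expected_response_per_generation(cfg0)
        slopes = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_founders=500,
                n_generations=5,
                offspring_per_dam=10,
                selection_intensity=0.2,
                selection_intensity_males=0.2,
                n_markers=0,
                seed=100 + seed,
            )
            ped, truth = simulate_pedigree(cfg)
            slopes.append(genetic_trend(truth.tbv, ped.birth_year, [1.0])[0])
        realized = float(np.mean(slopes))
        assert realized > 0
        assert abs(realized - expected) < 0.25 * expected

    def test_overselection_error_names_generation(self):
        cfg = SimulationConfig(n_founders=10, n_generations=3, selection_intensity=0.01)
        with pytest.raises(ValueError, match="generation 0"):
            simulate_pedigree(cfg)

    def test_founder_tbv_variance_near_additive_variance(self):
        cfg = SimulationConfig(n_founders=4000, n_generations=1, n_markers=500, seed=5)
        _, truth = simulate_pedigree(cfg)
        var = truth.tbv[:, 0].var()
        assert abs(var - 0.3) < 0.05


class TestSimulateGenotypes:
    def test_zero_markers_valid(self):
        cfg = SimulationConfig(n_founders=10, n_generations=1, n_markers=0, prop_genotyped=1.0)
        ped, _ = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        assert geno.n_markers == 0 and geno.n_animals == 10

    def test_founder_mean_code_matches_binomial_expectation(self):
        cfg = SimulationConfig(
            n_founders=200,
            n_generations=1,
            n_markers=1000,
            founder_maf_range=(0.5, 0.5),
            founder_haplotypes=None,
            prop_genotyped=1.0,
            seed=6,
        )
        ped, _ = simulate_pedigree(cfg)
        geno = simulate_genotypes(ped, cfg)
        mean = geno.codes.mean()
        se = np.sqrt(0.5 / geno.codes.size)
        assert abs(mean - 1.0) < 3 * se

    def test_mendelian_consistency_with_parents(self, small_data):
        """Offspring of two code-0 (code-2) parents at a marker are code 0
        (code 2) there."""
        ped, geno = small_data.pedigree, small_data.genotypes
        pos = {a: i for i, a in enumerate(geno.ids)}
        full = np.full(ped.n_animals, -1)
        for a, i in pos.items():
            full[ped.positions([a])[0]] = i
        kids = np.flatnonzero((ped.sire_idx >= 0) & (full >= 0))
        kids = kids[(full[ped.sire_idx[kids]] >= 0) & (full[ped.dam_idx[kids]] >= 0)]
        C = geno.codes[full[kids]]
        S = geno.codes[full[ped.sire_idx[kids]]]
        D = geno.codes[full[ped.dam_idx[kids]]]
        assert (C[(S == 0) & (D == 0)] == 0).all()
        assert (C[(S == 2) & (D == 2)] == 2).all()

    def test_frequency_preserved_across_replicate_drops(self):
        """Under random selection, descendant allele frequencies match the
        realized founder frequencies in expectation (20 replicates)."""
        diffs = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_founders=100,
                n_generations=3,
                selection_weights=(0.0,),
                n_markers=400,
                prop_genotyped=1.0,
                seed=400 + seed,
            )
            data = simulate(cfg)
            ped = data.pedigree
            rows_f = ped.positions(ped.ids[ped.sire_idx < 0])
            last = ped.birth_year == ped.birth_year.max()
            rows_l = ped.positions(ped.ids[last])
            pf = data.genotypes.codes[rows_f].mean(axis=0) / 2.0
            pl = data.genotypes.codes[rows_l].mean(axis=0) / 2.0
            diffs.append(pl - pf)
        diffs = np.array(diffs)
        mean = diffs.mean(axis=0)
        se = diffs.std(axis=0, ddof=1) / np.sqrt(20)
        frac_violating = np.mean(np.abs(mean) > 3 * se + 1e-12)
        assert frac_violating < 0.05


class TestSimulatePhenotypes:
    def test_heritability_one_gives_exact_tbv(self):
        cfg = SimulationConfig(
            n_founders=200,
            n_generations=1,
            n_markers=100,
            heritabilities=(1.0,),
            repeatability=(1.0,),
            prop_phenotyped_females=1.0,
            seed=7,
        )
        ped, truth = simulate_pedigree(cfg)
        phen = simulate_phenotypes(ped, truth, cfg)
        df = phen.frame
        tbv = truth.tbv[ped.positions(df["id"].to_numpy()), 0]
        resid = df["value"].to_numpy() - tbv
        # phenotype minus TBV equals the group effect, constant per level
        for _, grp in df.assign(r=resid).groupby("fixed_level"):
            assert np.ptp(grp["r"].to_numpy()) < 1e-12

    def test_variance_ratio_recovers_heritability(self):
        ratios = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_founders=5000,
                n_generations=1,
                n_markers=300,
                prop_phenotyped_females=1.0,
                max_records=1,
                cg_effect_sd=0.0,
                seed=600 + seed,
            )
            data = simulate(cfg)
            df = data.phenotypes.frame
            tbv = data.truth.tbv[data.pedigree.positions(df["id"].to_numpy()), 0]
            ratios.append(tbv.var() / df["value"].to_numpy().var())
        assert abs(np.mean(ratios) - 0.3) < 0.03

    def test_repeatability_equal_h2_zeroes_permanent_env(self):
        cfg = SimulationConfig(
            n_founders=100, n_generations=1, n_markers=50, repeatability=(0.3,), seed=8
        )
        _, truth = simulate_pedigree(cfg)
        assert np.all(truth.pe == 0.0)


class TestPartition:
    def _toy(self):
        # 5 genotyped: 3 with phenotypes, 2 young with neither
        ids = np.arange(1, 6)
        ped = Pedigree(ids, np.zeros(5, int), np.zeros(5, int), [2000] * 3 + [2005] * 2, ["F"] * 5)
        import pandas as pd

        from igpipe.population import GenotypeMatrix, PhenotypeRecords

        phen = PhenotypeRecords(
            pd.DataFrame(
                {
                    "id": [1, 2, 3],
                    "trait": 0,
                    "value": [1.0, 2.0, 3.0],
                    "fixed_level": "a",
                    "record_no": 1,
                }
            )
        )
        geno = GenotypeMatrix(ids, np.zeros((5, 2), int))
        return ped, phen, geno

    def test_toy_shares_sixty_forty(self):
        ped, phen, geno = self._toy()
        part = partition_animals(ped, phen, geno, cutoff_year=2005)
        assert part.shares == {"gebv": 60, "igp": 40}
        assert set(part.igp_ids) == {4, 5}

    def test_sire_with_progeny_but_no_phenotype_in_gebv_set(self):
        import pandas as pd

        from igpipe.population import GenotypeMatrix, PhenotypeRecords

        ped = Pedigree([1, 2, 3], [0, 0, 1], [0, 0, 2], [2004, 2004, 2005], ["M", "F", "F"])
        phen = PhenotypeRecords(
            pd.DataFrame(
                {"id": [2], "trait": 0, "value": [1.0], "fixed_level": "a", "record_no": 1}
            )
        )
        geno = GenotypeMatrix([1, 3], np.zeros((2, 3), int))
        part = partition_animals(ped, phen, geno, cutoff_year=2005)
        assert 1 in part.gebv_ids  # progeny, no phenotype
        assert 3 in part.igp_ids

    def test_genotyped_animal_missing_from_pedigree_errors(self):
        ped, phen, geno = self._toy()
        from igpipe.population import GenotypeMatrix

        bad = GenotypeMatrix([1, 99], np.zeros((2, 2), int))
        with pytest.raises(KeyError, match="99"):
            partition_animals(ped, phen, bad, cutoff_year=2005)

    def test_partition_exhaustive_and_disjoint(self, small_data):
        cfg = small_data.config
        part = partition_animals(
            small_data.pedigree,
            small_data.phenotypes,
            small_data.genotypes,
            cfg.start_year + cfg.n_generations - 1,
        )
        union = np.union1d(part.gebv_ids, part.igp_ids)
        assert np.array_equal(union, np.sort(small_data.genotypes.ids))
        everyone = np.concatenate([part.gebv_ids, part.igp_ids, part.nongenotyped_ids])
        assert np.array_equal(np.sort(everyone), small_data.pedigree.ids)
        # every IGP member is young, progeny-free and phenotype-free
        ped = small_data.pedigree
        pos = ped.positions(part.igp_ids)
        assert (ped.birth_year[pos] >= part.cutoff_year).all()
        assert not ped.has_progeny()[pos].any()
        assert not np.isin(part.igp_ids, small_data.phenotypes.animal_ids).any()


def test_simulation_deterministic_given_seed():
    cfg = SimulationConfig(n_founders=80, n_generations=3, n_markers=60, missing_rate=0.02, seed=12)
    d1, d2 = simulate(cfg), simulate(cfg)
    assert np.array_equal(d1.pedigree.ids, d2.pedigree.ids)
    assert np.array_equal(d1.truth.tbv, d2.truth.tbv)
    assert np.array_equal(d1.genotypes.codes, d2.genotypes.codes)
    assert d1.phenotypes.frame.equals(d2.phenotypes.frame)
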