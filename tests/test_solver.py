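import numpy as np
import pandas as pd
import pytest

from conftest import make_random_pedigree
from igpipe.genomic import allele_frequencies, build_G, center_genotypes
from igpipe.pedigree import build_A, build_A_inverse, compute_inbreeding, invert_dense_psd
from igpipe.population import GenotypeMatrix, PhenotypeRecords
from igpipe.simulate import SimulationConfig, simulate
from igpipe.solver import (
    ModelSpec,
    SolveOptions,
    VarianceComponents,
    assemble_H_inverse,
    build_mme,
    pcg_solve,
    run_ssgblup,
)


def make_records(rows):
    df = pd.DataFrame(rows, columns=["id", "trait", "value", "fixed_level"])
    df["record_no"] = df.groupby(["id", "trait"]).cumcount() + 1
    return PhenotypeRecords(df)


def dense_mme_oracle(phen, ped, vc, Hd, fit_pe):
    """Independent dense MME assembly from design matrices (single trait)."""
    wide = phen.wide(1)
    nrec = len(wide)
    levels, lidx = np.unique(wide["fixed_level"], return_inverse=True)
    apos = ped.positions(wide["id"].to_numpy())
    X = np.zeros((nrec, levels.size))
    X[np.arange(nrec), lidx] = 1
    W = np.zeros((nrec, ped.n_animals))
    W[np.arange(nrec), apos] = 1
    M = [X, W]
    if fit_pe:
        peA, pidx = np.unique(apos, return_inverse=True)
        Wp = np.zeros((nrec, peA.size))
        Wp[np.arange(nrec), pidx] = 1
        M.append(Wp)
    M = np.hstack(M)
    se = vc.residual[0, 0]
    C = M.T @ M / se
    nl = levels.size
    na = ped.n_animals
    C[nl : nl + na, nl : nl + na] += np.linalg.inv(Hd) / vc.additive[0, 0]
    if fit_pe:
        C[nl + na :, nl + na :] += np.eye(C.shape[0] - nl - na) / vc.permanent_env[0, 0]
    b = M.T @ wide["t0"].to_numpy() / se
    return C, b


class TestHInverseOperator:
    def test_without_genomics_equals_A_inverse(self):
        ped = make_random_pedigree(40, 10, seed=0)
        Ainv = build_A_inverse(ped)
        H = assemble_H_inverse(Ainv)
        v = np.random.default_rng(1).standard_normal(40)
        assert np.array_equal(H.matvec(v), Ainv @ v)

    def test_G_equal_A22_cancels(self):
        ped = make_random_pedigree(50, 12, seed=2)
        geno_ids = ped.ids[::2]
        A22 = build_A(ped, geno_ids)
        A22inv = invert_dense_psd(A22)
        H = assemble_H_inverse(build_A_inverse(ped), A22inv, A22inv, ped.positions(geno_ids))
        v = np.random.default_rng(3).standard_normal(50)
        assert np.abs(H.matvec(v) - build_A_inverse(ped) @ v).max() < 1e-8

    def test_matvec_matches_dense_assembly(self):
        ped = make_random_pedigree(80, 20, seed=4)
        geno_ids = ped.ids[10:40]
        rng = np.random.default_rng(5)
        geno = GenotypeMatrix(geno_ids, rng.integers(0, 3, (30, 100)))
        f = allele_frequencies(geno)
        G = build_G(center_genotypes(geno, f), f, geno_ids)
        Ginv = invert_dense_psd(G.matrix)
        A22inv = invert_dense_psd(build_A(ped, geno_ids))
        Ainv = build_A_inverse(ped)
        H = assemble_H_inverse(Ainv, Ginv, A22inv, ped.positions(geno_ids))
        dense = H.dense()
        v = rng.standard_normal(80)
        assert np.abs(H.matvec(v) - dense @ v).max() < 1e-8
        assert np.allclose(H.diagonal(), np.diag(dense))

    def test_dimension_mismatch_rejected(self):
        ped = make_random_pedigree(20, 5, seed=6)
        with pytest.raises(ValueError, match="genotyped"):
            assemble_H_inverse(build_A_inverse(ped), np.eye(3), np.eye(4), np.arange(3))


class TestBuildMme:
    def test_shrunken_mean_closed_form(self):
        """Three unrelated animals, one record each in one group: the MME
        solution matches the independently assembled dense system."""
        from igpipe.population import Pedigree

        ped = Pedigree([1, 2, 3], [0] * 3, [0] * 3, [2000] * 3, ["F"] * 3)
        vc = VarianceComponents.from_scalars(0.3, 0.7)
        phen = make_records([(1, 0, 1.0, "a"), (2, 0, 2.0, "a"), (3, 0, 4.0, "a")])
        Hinv = assemble_H_inverse(build_A_inverse(ped))
        sys_ = build_mme(phen, ped, ModelSpec(1), vc, Hinv)
        C, b = dense_mme_oracle(phen, ped, vc, build_A(ped), fit_pe=False)
        x = np.linalg.solve(C, b)
        res = pcg_solve(sys_.matvec, sys_.rhs, sys_.apply_precond, tol=1e-20)
        assert np.abs(res.x - x).max() < 1e-6
        # the EBV is the h2-shrunken within-group deviation
        mu = x[0]
        lam = 0.7 / 0.3
        assert x[1] == pytest.approx((1.0 - mu) / (1 + lam), rel=1e-6)

    def test_zero_phenotypes_give_zero_ebv(self):
        ped = make_random_pedigree(15, 5, seed=7)
        vc = VarianceComponents.from_scalars(0.3, 0.7)
        res = run_ssgblup(ped, None, PhenotypeRecords(pd.DataFrame(columns=PhenotypeRecords.COLUMNS)), vc, options=SolveOptions(genomic=False))
        assert np.all(res.gebv.values == 0.0)

    def test_repeated_records_match_dense_oracle(self):
        ped = make_random_pedigree(30, 8, seed=8)
        vc = VarianceComponents.from_scalars(0.3, 0.55, 0.15)
        rng = np.random.default_rng(9)
        rows = []
        for a in ped.ids[5:20]:
            for _ in range(rng.integers(1, 4)):
                rows.append((a, 0, rng.normal(), f"g{rng.integers(3)}"))
        phen = make_records(rows)
        Hinv = assemble_H_inverse(build_A_inverse(ped))
        sys_ = build_mme(phen, ped, ModelSpec(1), vc, Hinv)
        C, b = dense_mme_oracle(phen, ped, vc, build_A(ped), fit_pe=True)
        assert np.abs(sys_.rhs - b).max() < 1e-10
        assert np.abs(sys_.dense() - C).max() < 1e-10

    def test_uncorrelated_two_trait_model_separates(self):
        ped = make_random_pedigree(25, 6, seed=10)
        rng = np.random.default_rng(11)
        rows = []
        for a in ped.ids[4:18]:
            for t in (0, 1):
                rows.append((a, t, rng.normal(), "cg1"))
        phen = make_records(rows)
        Hinv = assemble_H_inverse(build_A_inverse(ped))
        vc2 = VarianceComponents(np.diag([0.3, 0.5]), np.diag([0.7, 0.5]))
        joint = build_mme(phen, ped, ModelSpec(2), vc2, Hinv)
        xj = pcg_solve(joint.matvec, joint.rhs, joint.apply_precond, tol=1e-20).x
        _, aj, _ = joint.split(xj)
        for t, (sa, se) in enumerate([(0.3, 0.7), (0.5, 0.5)]):
            single = PhenotypeRecords(phen.frame[phen.frame["trait"] == t].assign(trait=0))
            vc1 = VarianceComponents.from_scalars(sa, se)
            sys1 = build_mme(single, ped, ModelSpec(1), vc1, Hinv)
            x1 = pcg_solve(sys1.matvec, sys1.rhs, sys1.apply_precond, tol=1e-20).x
            _, a1, _ = sys1.split(x1)
            assert np.abs(aj[:, t] - a1[:, 0]).max() < 1e-8


class TestPcg:
    def test_identity_converges_in_one_iteration(self):
        b = np.array([1.0, -2.0, 3.0])
        res = pcg_solve(np.eye(3), b)
        assert res.iterations == 1 and np.allclose(res.x, b)

    def test_matches_dense_factorization(self):
        """PCG on an assembled ~350-equation system agrees with a dense
        factorization solve."""
        cfg = SimulationConfig(n_founders=120, n_generations=3, n_markers=100, seed=13)
        data = simulate(cfg)
        vc = data.variance_components
        Hinv = assemble_H_inverse(build_A_inverse(data.pedigree))
        sys_ = build_mme(data.phenotypes, data.pedigree, ModelSpec(1), vc, Hinv)
        assert sys_.n_equations <= 500
        dense = sys_.dense()
        x_dense = np.linalg.solve(dense, sys_.rhs)
        res = pcg_solve(sys_.matvec, sys_.rhs, sys_.apply_precond, tol=1e-16)
        assert res.converged
        assert np.abs(res.x - x_dense).max() < 1e-6 * np.abs(x_dense).max()

    def test_looser_tolerance_needs_no_more_iterations(self):
        rng = np.random.default_rng(14)
        B = rng.standard_normal((60, 80))
        A = B @ B.T / 80 + 0.5 * np.eye(60)
        b = rng.standard_normal(60)
        it_loose = pcg_solve(A, b, tol=1e-4).iterations
        it_tight = pcg_solve(A, b, tol=1e-12).iterations
        assert it_loose <= it_tight

    def test_non_convergence_flagged(self):
        rng = np.random.default_rng(15)
        B = rng.standard_normal((40, 50))
        A = B @ B.T / 50 + 1e-6 * np.eye(40)
        res = pcg_solve(A, rng.standard_normal(40), max_iter=2)
        assert not res.converged and res.final_criterion > 1e-12

    def test_zero_rhs_short_circuits(self):
        res = pcg_solve(np.eye(3), np.zeros(3))
        assert res.iterations == 0 and res.converged


class TestRunSsgblup:
    def test_pedigree_blup_equals_G_set_to_A22(self, small_data):
        from igpipe.genomic import GenomicRelationship

        d = small_data
        sub = d.genotypes.subset(d.genotypes.ids[:150])
        A22 = build_A(d.pedigree, sub.ids)
        G = GenomicRelationship(sub.ids, A22, k=1.0, beta=0.0)
        tight = SolveOptions(tol=1e-16)
        with_G = run_ssgblup(d.pedigree, sub, d.phenotypes, d.variance_components, options=tight, G=G)
        pblup = run_ssgblup(d.pedigree, None, d.phenotypes, d.variance_components, options=SolveOptions(genomic=False, tol=1e-16))
        assert np.abs(with_G.gebv.values - pblup.gebv.values).max() < 1e-6

    def test_apy_with_full_core_matches_direct_inverse(self, small_data):
        d = small_data
        sub = d.genotypes.subset(d.genotypes.ids[:200])
        direct = run_ssgblup(d.pedigree, sub, d.phenotypes, d.variance_components)
        apy = run_ssgblup(
            d.pedigree, sub, d.phenotypes, d.variance_components,
            options=SolveOptions(apy_core_ids=sub.ids),
        )
        sigma_a = d.variance_components.genetic_sd()[0]
        assert np.abs(direct.gebv.values - apy.gebv.values).max() < 1e-4 * sigma_a

    def test_solver_deterministic(self, small_data):
        d = small_data
        sub = d.genotypes.subset(d.genotypes.ids[:100])
        r1 = run_ssgblup(d.pedigree, sub, d.phenotypes, d.variance_components)
        r2 = run_ssgblup(d.pedigree, sub, d.phenotypes, d.variance_components)
        assert np.array_equal(r1.gebv.values, r2.gebv.values)
        assert r1.iterations == r2.iterations

    def test_genomic_information_improves_truth_recovery(self):
        """Single-step GBLUP beats pedigree BLUP on corr(EBV, TBV) for
        genotyped phenotyped animals, averaged over 5 seeds."""
        ss, pb = [], []
        for seed in range(5):
            cfg = SimulationConfig(
                n_founders=250,
                offspring_per_dam=7,
                n_generations=4,
                heritabilities=(0.4,),
                repeatability=(0.5,),
                n_markers=800,
                seed=700 + seed,
            )
            d = simulate(cfg)
            res_ss = run_ssgblup(d.pedigree, d.genotypes, d.phenotypes, d.variance_components)
            res_pb = run_ssgblup(d.pedigree, None, d.phenotypes, d.variance_components, options=SolveOptions(genomic=False))
            gp = d.genotypes.ids[np.isin(d.genotypes.ids, d.phenotypes.animal_ids)]
            tbv = d.truth.tbv[d.pedigree.positions(gp), 0]
            ss.append(np.corrcoef(res_ss.gebv.for_ids(gp)[:, 0], tbv)[0, 1])
            pb.append(np.corrcoef(res_pb.gebv.for_ids(gp)[:, 0], tbv)[0, 1])
        assert np.mean(ss) > np.mean(pb)
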