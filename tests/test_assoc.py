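"""Association stage: phenotype adjustment, OLS and mixed-model scans,
Wald p-values, genomic inflation, candidate calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vascgwas import assoc, qc, syndata
from conftest import make_matrix


def _samples(age, rhi, sex):
    return pd.DataFrame({"id": [f"S{i}" for i in range(len(age))],
                         "sex": sex, "age": age, "rhi": rhi})


def _adjusted_from_z(zvals, ids=None):
    """AdjustedPhenotype built directly from standardized values."""
    z = np.asarray(zvals, dtype=float)
    z = (z - z.mean()) / z.std(ddof=1)
    ids = ids or [f"S{i:04d}" for i in range(len(z))]
    table = pd.DataFrame({"id": ids, "sex": "M", "age": 60.0,
                          "rhi": z, "residual": z, "z": z})
    return assoc.AdjustedPhenotype(table, {"M": (0.0, 0.0)})


class TestAdjustPhenotype:
    def test_three_point_hand_ols(self):
        # M stratum: ages (50,60,70), rhi (2.0,1.9,1.5); hand OLS gives
        # slope -0.025, residuals (-0.05, 0.1, -0.05), z = +-0.5774, 1.1547
        s = _samples([50, 60, 70, 55, 65, 75],
                     [2.0, 1.9, 1.5, 2.2, 2.0, 1.7],
                     ["M", "M", "M", "F", "F", "F"])
        adj = assoc.adjust_phenotype(s)
        m = adj.table[adj.table["sex"] == "M"]
        np.testing.assert_allclose(
            m["z"], [-0.5773503, 1.1547005, -0.5773503], atol=1e-6)
        assert adj.fits["M"][1] == pytest.approx(-0.025)

    def test_zero_residual_variance_errors(self):
        s = _samples([50, 60, 70, 55, 65, 75],
                     [2.0, 1.9, 1.8, 2.2, 2.0, 1.8],
                     ["M", "M", "M", "F", "F", "F"])
        with pytest.raises(ValueError, match="residual variance"):
            assoc.adjust_phenotype(s)

    def test_small_stratum_errors(self):
        s = _samples([50, 60, 70, 55], [2.0, 1.9, 1.5, 2.2],
                     ["M", "M", "M", "F"])
        with pytest.raises(ValueError, match="F"):
            assoc.adjust_phenotype(s)

    def test_per_stratum_standardization_invariant(self, genome):
        G = syndata.simulate_genotypes(genome, 80, 10, seed=50)
        s = syndata.simulate_phenotypes(G, seed=51)
        adj = assoc.adjust_phenotype(s)
        for _, sub in adj.table.groupby("sex"):
            assert abs(sub["z"].mean()) < 1e-10
            assert abs(sub["z"].std(ddof=1) - 1) < 1e-10

    def test_order_invariance(self, genome):
        G = syndata.simulate_genotypes(genome, 40, 5, seed=52)
        s = syndata.simulate_phenotypes(G, seed=53)
        shuffled = s.sample(frac=1, random_state=1).reset_index(drop=True)
        a = assoc.adjust_phenotype(s).table.set_index("id")["z"]
        b = assoc.adjust_phenotype(shuffled).table.set_index("id")["z"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


class TestWaldP:
    def test_zero_effect_gives_one(self):
        assert assoc.wald_p(0.0, 1.0) == 1.0

    def test_symmetric_and_monotone(self):
        assert assoc.wald_p(1.5, 0.3) == assoc.wald_p(-1.5, 0.3)
        ps = [assoc.wald_p(b, 1.0) for b in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_survival_function_tail_precision(self):
        # 1 - cdf loses all precision past z ~ 8; the survival function
        # stays accurate deep into the tail
        assert 0 < assoc.wald_p(35.0, 1.0) < 1e-200
        assert assoc.wald_p(9.0, 1.0) == pytest.approx(2 * stats.norm.sf(9.0))

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            assoc.wald_p(1.0, 0.0)


class TestAssocLinear:
    def test_matches_closed_form_six_samples(self):
        x = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        z = np.array([0.2, 0.5, 1.4, 0.3, -0.8, 1.0])
        G = make_matrix(x[:, None], ids=[f"S{i:04d}" for i in range(6)])
        adj = _adjusted_from_z(z)
        rec = assoc.assoc_linear(G, adj)
        # textbook OLS (X'X)^-1 X'y on the standardized z
        zz = (z - z.mean()) / z.std(ddof=1)
        W = np.column_stack([np.ones(6), x])
        coef = np.linalg.solve(W.T @ W, W.T @ zz)
        resid = zz - W @ coef
        s2 = resid @ resid / 4
        se = np.sqrt(s2 * np.linalg.inv(W.T @ W)[1, 1])
        assert rec["b"].iloc[0] == pytest.approx(coef[1], abs=1e-10)
        assert rec["se"].iloc[0] == pytest.approx(se, abs=1e-10)
        assert rec["p"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(abs(coef[1] / se)), rel=1e-10)

    def test_zero_variance_snp_flagged(self):
        G = make_matrix(np.column_stack([np.ones(6), [0, 1, 2, 0, 1, 2]]),
                        ids=[f"S{i:04d}" for i in range(6)])
        adj = _adjusted_from_z([0.1, 0.4, -0.2, 0.9, -1.1, 0.5])
        rec = assoc.assoc_linear(G, adj)
        assert np.isnan(rec["p"].iloc[0])
        assert np.isfinite(rec["p"].iloc[1])

    def test_missing_dosage_complete_case(self):
        x = np.array([0, 1, 2, 1, np.nan, 2])
        z = np.array([0.2, 0.5, 1.4, 0.3, -0.8, 1.0])
        G = make_matrix(x[:, None], ids=[f"S{i:04d}" for i in range(6)])
        rec = assoc.assoc_linear(G, _adjusted_from_z(z))
        ok = np.isfinite(x)
        zz = (z - z.mean()) / z.std(ddof=1)
        b_cc = np.polyfit(x[ok], zz[ok], 1)[0]
        assert rec["b"].iloc[0] == pytest.approx(b_cc, abs=1e-10)

    def test_null_pvalues_uniform_ks(self, genome):
        # KS at alpha=0.01 across 3 seeds, allowing one expected failure
        passes = 0
        for seed in (60, 61, 62):
            G = syndata.simulate_genotypes(genome, 150, 2000, seed=seed)
            adj = _adjusted_from_z(
                np.random.default_rng(seed + 1000).normal(size=150),
                ids=G.sample_ids)
            rec = assoc.assoc_linear(G, adj)
            ks = stats.kstest(rec["p"].dropna(), "uniform")
            passes += ks.pvalue > 0.01
        assert passes >= 2

    def test_planted_causal_snp_ranks_top(self, genome):
        # power check: effect 0.5 SD at n=500 lands in the p top-10
        hits = 0
        for seed in range(20):
            G = syndata.simulate_genotypes(genome, 500, 300, seed=70 + seed)
            rng = np.random.default_rng(170 + seed)
            x = G.dosages[:, 42]
            z = 0.5 * x + rng.normal(size=500)
            rec = assoc.assoc_linear(G, _adjusted_from_z(z, ids=G.sample_ids))
            rank = rec.sort_values("p").index.get_loc(42)
            hits += rank < 10
        assert hits >= 19

    def test_covariates_absorb_confounder(self, genome):
        G = syndata.simulate_genotypes(genome, 200, 50, seed=80)
        rng = np.random.default_rng(81)
        c = rng.normal(size=200)
        z = 2.0 * c + rng.normal(size=200)
        cov = pd.DataFrame({"id": G.sample_ids, "c": c})
        rec = assoc.assoc_linear(G, _adjusted_from_z(z, ids=G.sample_ids), cov)
        assert np.isfinite(rec["p"]).all()


class TestMlm:
    def test_identity_grm_recovers_total_variance(self):
        rng = np.random.default_rng(90)
        y = rng.normal(size=100)
        adj = _adjusted_from_z(y)
        grm = qc.Grm(list(adj.table["id"]), np.eye(100), 1000)
        fit = assoc.fit_mlm_null(adj, grm)
        total = fit.sigma_g2 + fit.sigma_e2
        assert total == pytest.approx(np.var(adj.table["z"], ddof=1), abs=1e-6)

    def test_mlm_equals_linear_when_no_genetic_variance(self, genome):
        G = syndata.simulate_genotypes(genome, 60, 100, seed=91)
        rng = np.random.default_rng(92)
        adj = _adjusted_from_z(rng.normal(size=60), ids=G.sample_ids)
        grm = qc.compute_grm(G)
        fit = assoc.fit_mlm_null(adj, grm)
        forced = assoc.MlmFit(0.0, fit.sigma_g2 + fit.sigma_e2, 0.0,
                              fit.loglik, True, fit.eigvals, fit.eigvecs,
                              fit.sample_ids)
        lm = assoc.assoc_linear(G, adj)
        mlm = assoc.assoc_mlm(G, adj, grm, forced)
        np.testing.assert_allclose(mlm["b"], lm["b"], atol=1e-8)
        np.testing.assert_allclose(mlm["se"], lm["se"], atol=1e-8)

    def test_diagonal_v_matches_weighted_ols(self):
        # 5-sample hand instance: V diagonal -> GLS = weighted OLS
        x = np.array([0.0, 1, 2, 1, 0])
        y = np.array([0.1, 0.9, 1.8, 1.2, -0.3])
        adj = _adjusted_from_z(y)
        d = np.array([1.0, 2.0, 0.5, 1.0, 3.0])
        grm = qc.Grm(list(adj.table["id"]), np.diag(d), 10)
        fit = assoc.fit_mlm_null(adj, grm)
        G = make_matrix(x[:, None], ids=list(adj.table["id"]))
        rec = assoc.assoc_mlm(G, adj, grm, fit)
        V = fit.sigma_g2 * np.diag(d) + fit.sigma_e2 * np.eye(5)
        Vi = np.linalg.inv(V)
        W = np.column_stack([np.ones(5), x])
        zz = adj.table["z"].to_numpy()
        cov = np.linalg.inv(W.T @ Vi @ W)
        coef = cov @ W.T @ Vi @ zz
        r = zz - W @ coef
        phi = r @ Vi @ r / 3
        assert rec["b"].iloc[0] == pytest.approx(coef[1], abs=1e-8)
        assert rec["se"].iloc[0] == pytest.approx(
            np.sqrt(phi * cov[1, 1]), abs=1e-8)

    def test_h2_recovery_structured(self, genome):
        # short-loop parameter recovery; the full 50-replicate version is
        # part of the acceptance checks
        G, _ = syndata.simulate_structured_genotypes(genome, (100, 100), 800,
                                                     seed=93)
        grm = qc.compute_grm(G)
        A = (grm.matrix + grm.matrix.T) / 2
        lam, U = np.linalg.eigh(A)
        lam = np.clip(lam, 0, None)
        rng = np.random.default_rng(94)
        h2s = []
        for _ in range(10):
            g = U @ (np.sqrt(0.5 * lam) * rng.normal(size=200))
            y = g + rng.normal(0, np.sqrt(0.5), size=200)
            fit = assoc.fit_mlm_null(_adjusted_from_z(y, ids=G.sample_ids), grm)
            h2s.append(fit.h2)
        assert abs(np.mean(h2s) - 0.5) < 0.15

    def test_null_h2_near_zero(self, genome):
        # pure-noise phenotype on an identifiable (structured) GRM: the
        # REML estimate collapses to the boundary in >= 90% of replicates
        G, _ = syndata.simulate_structured_genotypes(genome, (250, 250),
                                                     1000, fst=0.1, seed=95)
        grm = qc.compute_grm(G)
        rng = np.random.default_rng(96)
        low = sum(assoc.fit_mlm_null(
            _adjusted_from_z(rng.normal(size=500), ids=G.sample_ids),
            grm).h2 <= 0.1 for _ in range(10))
        assert low >= 9

    def test_mlm_deflates_lambda_on_related_cohort(self, genome):
        # phenotypic resemblance among relatives inflates the linear scan;
        # the mixed model absorbs it
        G, labels = syndata.simulate_structured_genotypes(
            genome, (100, 100), 1500, fst=0.1, seed=97)
        rng = np.random.default_rng(98)
        y = labels * 1.0 + rng.normal(size=200)
        adj = _adjusted_from_z(y, ids=G.sample_ids)
        grm = qc.compute_grm(G)
        lam_lm = assoc.genomic_lambda(assoc.assoc_linear(G, adj))
        fit = assoc.fit_mlm_null(adj, grm)
        lam_mlm = assoc.genomic_lambda(assoc.assoc_mlm(G, adj, grm, fit))
        assert lam_mlm <= lam_lm


class TestGenomicLambda:
    def test_unit_lambda_at_null_median(self):
        rec = pd.DataFrame({"b": np.full(5, np.sqrt(assoc.CHI2_1_MEDIAN)),
                            "se": np.ones(5)})
        assert assoc.genomic_lambda(rec) == pytest.approx(1.0)

    def test_null_simulation_in_band(self, genome):
        G = syndata.simulate_genotypes(genome, 200, 2000, seed=99)
        adj = _adjusted_from_z(
            np.random.default_rng(100).normal(size=200), ids=G.sample_ids)
        lam = assoc.genomic_lambda(assoc.assoc_linear(G, adj))
        assert 0.9 <= lam <= 1.1


class TestCallCandidates:
    @pytest.fixture
    def records(self):
        return pd.DataFrame({
            "id": ["1:100", "1:5000", "2:300"],
            "chr": ["1", "1", "2"], "bp": [100, 5000, 300],
            "a1": "A", "a2": "C", "freq": 0.2,
            "b": [1.0, 2.0, -1.5], "se": [0.2, 0.3, 0.25],
            "p": [4e-5, 5e-5, 1e-9], "model": "lm"})

    @pytest.fixture
    def genes(self):
        return pd.DataFrame({
            "chr": ["1", "1", "2"], "start": [50, 1100, 200],
            "end": [150, 3900, 400], "name": ["gA", "gB", "gC"]})

    def test_strict_threshold_boundary(self, records, genes):
        out = assoc.call_candidates(records, genes)
        assert set(out["id"]) == {"1:100", "2:300"}  # p=5e-5 excluded

    def test_tiers_and_containment(self, records, genes):
        out = assoc.call_candidates(records, genes)
        row = out[out["id"] == "2:300"].iloc[0]
        assert row["tier"] == "genomewide"
        assert row["closest_gene"] == "gC" and row["gene_distance"] == 0

    def test_equidistant_tie_breaks_to_smaller_start(self):
        rec = pd.DataFrame({"id": ["1:2500"], "chr": ["1"], "bp": [2500],
                            "a1": "A", "a2": "C", "freq": 0.1,
                            "b": [2.0], "se": [0.3], "p": [1e-6],
                            "model": "lm"})
        genes = pd.DataFrame({"chr": ["1", "1"],
                              "start": [100, 4000], "end": [1500, 6000],
                              "name": ["left", "right"]})
        out = assoc.call_candidates(rec, genes)  # 1000 bp to either side
        assert out["closest_gene"].iloc[0] == "left"

    def test_no_same_chromosome_gene_unannotated(self, records):
        genes = pd.DataFrame({"chr": ["9"], "start": [10], "end": [20],
                              "name": ["far"]})
        out = assoc.call_candidates(records, genes)
        assert (out["closest_gene"] == "").all()

    def test_order_independence(self, records, genes):
        a = assoc.call_candidates(records, genes)
        b = assoc.call_candidates(records.sample(frac=1, random_state=3),
                                  genes)
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))
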