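"""Trait imputation, NRMSE reliability, and strategy-axis extraction."""

import numpy as np
import pandas as pd
import pytest

from overyield import synth
from overyield.traits import (
    TRAITS,
    assess_nrmse,
    impute_traits,
    phylo_eigenvectors,
    strategy_axes,
)


class TestImputeTraits:
    def test_complete_matrix_is_identity(self, pool):
        matrix, _ = pool
        complete, provenance = impute_traits(matrix, seed=0)
        pd.testing.assert_frame_equal(complete, matrix[TRAITS].astype(float))
        assert (provenance == "measured").all().all()

    def test_gaps_filled_and_flagged(self, pool_gappy):
        matrix, _ = pool_gappy
        complete, provenance = impute_traits(matrix, seed=0, fast=True)
        assert complete.notna().all().all()
        assert ((provenance == "imputed") == matrix[TRAITS].isna()).all().all()

    def test_deterministic_given_seed(self, pool_gappy):
        matrix, _ = pool_gappy
        a, _ = impute_traits(matrix, seed=5, fast=True)
        b, _ = impute_traits(matrix, seed=5, fast=True)
        pd.testing.assert_frame_equal(a, b)

    def test_species_without_any_trait_excluded(self, pool_gappy):
        matrix, _ = pool_gappy
        matrix = matrix.copy()
        matrix.iloc[0, :] = np.nan
        complete, provenance = impute_traits(matrix, seed=0, fast=True)
        assert matrix.index[0] not in complete.index
        assert provenance.attrs["excluded_species"] == [matrix.index[0]]

    def test_imputed_values_track_truth(self, pool_gappy):
        matrix, truth = pool_gappy
        complete_truth, _ = synth.make_species_pool(200, seed=11, missingness=0.0)
        complete, _ = impute_traits(matrix, seed=0)
        mask = matrix[TRAITS].isna()
        est = np.log10(complete.to_numpy())[mask.to_numpy()]
        tru = np.log10(complete_truth.loc[complete.index, TRAITS].to_numpy())[mask.to_numpy()]
        r = np.corrcoef(est, tru)[0, 1]
        assert r > 0.7

    def test_missing_root_block_recovered_from_leaves(self, pool_gappy):
        matrix, _ = pool_gappy
        matrix = matrix.copy()
        sp = matrix.index[3]
        matrix.loc[sp, ["SRL", "RNC", "RTD"]] = np.nan
        matrix.loc[sp, ["SLA", "LNC", "LDMC"]] = matrix.loc[sp, ["SLA", "LNC", "LDMC"]].fillna(20.0)
        complete, provenance = impute_traits(matrix, seed=0, fast=True)
        assert complete.loc[sp].notna().all()
        assert (provenance.loc[sp, ["SRL", "RNC", "RTD"]] == "imputed").all()


class TestAssessNrmse:
    def test_perfect_imputer_scores_zero(self, pool_gappy):
        matrix, _ = pool_gappy
        complete_truth, _ = synth.make_species_pool(200, seed=11, missingness=0.0)

        def perfect(masked, seed):
            return complete_truth

        table = assess_nrmse(matrix, n_repeats=3, seed=0, imputer=perfect)
        assert np.allclose(table["nrmse"].dropna(), 0.0)

    def test_constant_mean_imputer_approaches_sd_over_range(self, rng):
        # uniform trait: sd/range = 1/sqrt(12) ~ 0.289 at large n
        n = 2000
        base = pd.DataFrame(
            {t: 10 ** rng.uniform(0.0, 1.0, n) for t in TRAITS},
            index=[f"sp{i}" for i in range(n)],
        )

        def mean_imputer(masked, seed):
            logm = np.log10(masked)
            return 10 ** logm.fillna(logm.mean())

        table = assess_nrmse(base, mask_fraction=0.2, n_repeats=2, seed=0,
                             imputer=mean_imputer)
        assert table["nrmse"].dropna().between(0.25, 0.33).all()

    def test_noisier_imputer_never_scores_better(self, pool_gappy):
        matrix, _ = pool_gappy

        def make_noisy(scale):
            def imputer(masked, seed):
                complete, _ = impute_traits(masked, seed=seed, fast=True)
                noisy = complete * 10 ** np.random.default_rng(seed).normal(
                    0.0, scale, complete.shape
                )
                return noisy
            return imputer

        quiet = assess_nrmse(matrix, n_repeats=2, seed=3, imputer=make_noisy(0.0))
        loud = assess_nrmse(matrix, n_repeats=2, seed=3, imputer=make_noisy(0.5))
        assert (loud["nrmse"].dropna() >= quiet["nrmse"].dropna()).all()

    def test_sparse_trait_reported_undefined(self, pool_gappy):
        matrix, _ = pool_gappy
        matrix = matrix.copy()
        matrix.loc[matrix.index[4:], "RTD"] = np.nan  # only 4 measured values
        table = assess_nrmse(matrix, n_repeats=2, seed=0,
                             imputer=lambda m, s: impute_traits(m, seed=s, fast=True)[0])
        assert np.isnan(table.loc["RTD", "nrmse"])


class TestStrategyAxes:
    def test_latent_acquisitiveness_recovered_by_pc1(self, pool):
        matrix, truth = pool
        scores = strategy_axes(matrix)
        r = np.corrcoef(scores.scores["PC1"], truth.g)[0, 1]
        assert r > 0.9
        # orientation: acquisitive marker loads positive on both axes
        assert scores.loadings.loc["SLA", "PC1"] > 0
        assert scores.loadings.loc["LNC", "PC2"] > 0

    def test_sign_flip_of_input_leaves_oriented_scores_invariant(self, pool):
        matrix, _ = pool
        a = strategy_axes(matrix)
        flipped = matrix.copy()
        # inverting a trait (e.g. 1/LDMC) flips its log-scale sign convention
        for t in TRAITS:
            flipped[t] = 1.0 / flipped[t]
        b = strategy_axes(flipped)
        # same axes up to orientation; the oriented scores must agree on PC1
        r = np.corrcoef(a.scores["PC1"], b.scores["PC1"])[0, 1]
        assert abs(r) > 0.999
        assert b.loadings.loc["SLA", "PC1"] > 0

    def test_duplicating_species_preserves_loadings_and_variance(self, pool):
        matrix, _ = pool
        a = strategy_axes(matrix)
        b = strategy_axes(pd.concat([matrix, matrix]))
        np.testing.assert_allclose(a.variance_explained, b.variance_explained, atol=1e-9)
        np.testing.assert_allclose(a.loadings.abs(), b.loadings.abs(), atol=1e-6)

    def test_scores_centered_unit_variance_orthogonal(self, pool):
        matrix, _ = pool
        s = strategy_axes(matrix).scores
        np.testing.assert_allclose(s.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(s.std(ddof=1), 1.0, rtol=1e-9)
        assert abs(np.corrcoef(s["PC1"], s["PC2"])[0, 1]) < 1e-9

    def test_two_axes_reconstruction_error_matches_unexplained_variance(self, pool):
        matrix, _ = pool
        sa = strategy_axes(matrix)
        logm = np.log10(matrix[TRAITS].to_numpy())
        Z = (logm - logm.mean(0)) / logm.std(0, ddof=1)
        # rank-2 reconstruction from scores and loadings
        recon = sa.scores.to_numpy() @ sa.loadings.to_numpy().T
        resid_frac = np.linalg.norm(Z - recon) ** 2 / np.linalg.norm(Z) ** 2
        expected = 1.0 - sa.variance_explained[:2].sum()
        assert resid_frac == pytest.approx(expected, rel=1e-6)

    def test_constant_trait_rejected_by_name(self, pool):
        matrix, _ = pool
        bad = matrix.copy()
        bad["SRL"] = 5.0
        with pytest.raises(ValueError, match="SRL"):
            strategy_axes(bad)

    def test_rank_one_structure_puts_all_variance_on_pc1(self):
        g = np.linspace(-2, 2, 50)
        matrix = pd.DataFrame(
            {t: 10 ** (0.1 * (s * g))
             for t, s in zip(TRAITS, [1, 1, -1, 1, 1, -1])},
            index=[f"sp{i}" for i in range(50)],
        )
        with pytest.raises(ValueError, match="rank"):
            strategy_axes(matrix)


class TestPhyloEigenvectors:
    def test_pcoa_of_patristic_distances(self):
        import dendropy

        newick = "((A:1,B:1):2,(C:1.5,D:1.5):1.5);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        vecs = phylo_eigenvectors(tree, ["A", "B", "C", "D"], n_vectors=3)
        assert list(vecs.index) == ["A", "B", "C", "D"]
        # first axis separates the two clades
        assert np.sign(vecs.iloc[0, 0]) == np.sign(vecs.iloc[1, 0])
        assert np.sign(vecs.iloc[0, 0]) != np.sign(vecs.iloc[2, 0])
        # eigenvector coordinates reproduce the pairwise distances (ultrametric-ish case)
        d_ab = np.linalg.norm(vecs.iloc[0] - vecs.iloc[1])
        assert d_ab == pytest.approx(2.0, rel=0.1)

    def test_usable_as_imputation_covariates(self, pool_gappy):
        import dendropy

        matrix, _ = pool_gappy
        sub = matrix.iloc[:12]
        taxa = list(sub.index)
        newick = "(" * (len(taxa) - 1) + taxa[0] + ":1," + "):1,".join(
            t + ":1" for t in taxa[1:]
        ) + ":1);"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        vecs = phylo_eigenvectors(tree, taxa, n_vectors=4)
        complete, _ = impute_traits(sub, phylo_covariates=vecs, seed=0, fast=True)
        assert complete.notna().all().all()
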