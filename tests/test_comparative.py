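"""Consensus trees, phylogenetic covariance and the Bayesian mixed model."""

import dendropy
import numpy as np
import pandas as pd
import pytest

import mungomhc as m


BETAS = dict(intercept=1.8, status=-0.4, log10n=0.25, exons=0.1,
             mhc_class=-0.35)
VARIANCES = dict(species=0.02, phylo=0.02, resid=0.02)


def clade_lengths(tree):
    out = {}
    for node in tree.preorder_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        out[clade] = node.edge.length
    return out


class TestConsensusTree:
    T1 = "((A:1,B:1):1,(C:1,D:1):1);"
    T2 = "((A:1,B:3):3,(C:1,D:1):1);"

    def test_identical_inputs_return_the_same_tree(self):
        cons = m.consensus_tree([self.T1, self.T1])
        got = clade_lengths(cons)
        assert got[frozenset({"A", "B"})] == 1.0
        assert got[frozenset({"C", "D"})] == 1.0
        assert got[frozenset({"B"})] == 1.0

    def test_shared_bipartition_gets_averaged_length(self):
        cons = m.consensus_tree([self.T1, self.T2])
        got = clade_lengths(cons)
        assert got[frozenset({"A", "B"})] == pytest.approx(2.0)  # mean(1, 3)
        assert got[frozenset({"B"})] == pytest.approx(2.0)
        assert got[frozenset({"C", "D"})] == pytest.approx(1.0)

    def test_minority_bipartition_collapses_to_polytomy(self):
        t3 = "((A:1,C:1):1,(B:1,D:1):1);"
        cons = m.consensus_tree([self.T1, self.T2, t3])
        clades = set(clade_lengths(cons))
        assert frozenset({"A", "B"}) in clades          # 2/3 of trees
        assert frozenset({"A", "C"}) not in clades      # 1/3 of trees
        assert frozenset({"B", "D"}) not in clades

    def test_tip_set_mismatch_is_reported(self):
        with pytest.raises(ValueError, match="tip sets differ"):
            m.consensus_tree([self.T1, "((A:1,B:1):1,(C:1,E:1):1);"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            m.consensus_tree([])


class TestPhyloCovariance:
    def test_star_tree_gives_identity(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1);", schema="newick")
        cov = m.phylo_covariance(tree, ["A", "B", "C"])
        assert np.allclose(cov.to_numpy(), np.eye(3))

    def test_sisters_share_depth_of_their_ancestor(self):
        tree = dendropy.Tree.get(data="((A:0.5,B:0.5):0.5,C:1);",
                                 schema="newick")
        cov = m.phylo_covariance(tree, ["A", "B", "C"])
        assert cov.loc["A", "B"] == pytest.approx(0.5)  # 1 - d, d = 0.5
        assert cov.loc["A", "C"] == pytest.approx(0.0)
        assert np.allclose(np.diag(cov), 1.0)

    def test_substituted_species_copies_proxy_row(self):
        tree = dendropy.Tree.get(data="((A:0.5,B:0.5):0.5,C:1);",
                                 schema="newick")
        cov = m.phylo_covariance(tree, ["A", "B", "C", "X"],
                                 substitutions={"X": "A"})
        assert cov.loc["X", "B"] == cov.loc["A", "B"]
        assert cov.loc["X", "C"] == cov.loc["A", "C"]
        assert cov.loc["X", "X"] == 1.0
        assert cov.loc["X", "A"] < 1.0  # jitter keeps the matrix invertible

    def test_unmapped_species_is_an_error(self):
        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        with pytest.raises(ValueError, match="not on tree"):
            m.phylo_covariance(tree, ["A", "Z"])


@pytest.fixture(scope="module")
def fitted_model(request):
    import random
    import dendropy.simulate
    tns = dendropy.TaxonNamespace([f"sp{i:02d}" for i in range(30)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=30,
        taxon_namespace=tns, rng=random.Random(17))
    table, truth = m.simulate_comparative_dataset(
        tree, BETAS, VARIANCES, n_obs_per_species=2, seed=17)
    cov = m.phylo_covariance(tree, sorted(table["species"].unique()))
    fit = m.fit_phylo_lmm(table, cov, n_iter=1500, warmup=500, chains=2,
                          seed=17)
    return tree, table, truth, cov, fit


class TestPhyloLMM:
    def test_recovers_status_slope(self, fitted_model):
        _, table, truth, cov, fit = fitted_model
        c = fit.coef("status")
        assert c["ci"][0] <= BETAS["status"] <= c["ci"][1]

    def test_lambda_in_unit_interval_for_every_draw(self, fitted_model):
        *_, fit = fitted_model
        lam = fit.draws["lambda"]
        assert np.all((lam >= 0) & (lam <= 1))

    def test_zero_phylo_variance_gives_small_lambda(self, birth_death_tree):
        tree = birth_death_tree(n_tips=25, seed=23)
        table, _ = m.simulate_comparative_dataset(
            tree, BETAS, dict(species=0.03, phylo=0.0, resid=0.02),
            n_obs_per_species=2, seed=23)
        cov = m.phylo_covariance(tree, sorted(table["species"].unique()))
        fit = m.fit_phylo_lmm(table, cov, n_iter=1200, warmup=400, chains=2,
                              seed=5)
        assert fit.lambda_mean < 0.3
        assert fit.lambda_ci[0] < 0.05

    def test_gibbs_matches_gls_with_variances_fixed_at_truth(self,
                                                             fitted_model):
        tree, table, truth, cov, _ = fitted_model
        from mungomhc.comparative import _design
        X, y, species, sp_idx = _design(table)
        fit = m.fit_phylo_lmm(table, cov, n_iter=3000, warmup=500, chains=2,
                              seed=3, fix_variances=dict(**{
                                  "species": VARIANCES["species"],
                                  "phylo": VARIANCES["phylo"],
                                  "resid": VARIANCES["resid"]}))
        S = len(species)
        Z = np.zeros((len(y), S))
        Z[np.arange(len(y)), sp_idx] = 1.0
        C = cov.loc[species, species].to_numpy()
        V = (VARIANCES["species"] * Z @ Z.T
             + VARIANCES["phylo"] * Z @ C @ Z.T
             + VARIANCES["resid"] * np.eye(len(y)))
        Vinv = np.linalg.inv(V)
        gls = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        post_means = np.array([fit.summary.loc[k, "mean"]
                               for k in ["intercept", "status", "log10n",
                                         "exons", "mhc_class"]])
        assert np.allclose(post_means, gls, atol=0.05)

    def test_non_psd_covariance_rejected(self, fitted_model):
        _, table, *_ = fitted_model
        species = sorted(table["species"].unique())
        bad = pd.DataFrame(-np.ones((len(species), len(species))),
                           index=species, columns=species)
        with pytest.raises(ValueError, match="positive"):
            m.fit_phylo_lmm(table, bad, n_iter=10, warmup=1, chains=1)

    def test_unknown_status_code_rejected(self, fitted_model):
        tree, table, truth, cov, _ = fitted_model
        broken = table.copy()
        broken.loc[0, "iucn_status"] = "XX"
        with pytest.raises(ValueError, match="IUCN"):
            m.fit_phylo_lmm(broken, cov, n_iter=10, warmup=1, chains=1)


class TestPredictAndFlag:
    def test_extreme_outlier_is_flagged_and_center_is_not(self, fitted_model):
        _, table, truth, cov, fit = fitted_model
        preds, flagged = m.predict_and_flag(fit, table, seed=0)
        assert list(preds.index) == [1, 2, 3, 4, 5]
        assert (preds["ci_low"] <= preds["mean"]).all()
        assert (preds["mean"] <= preds["ci_high"]).all()
        # inject a +5 SD outlier
        outlier = table.iloc[[0]].copy()
        sd = float(np.std(np.log10(table["n_alleles"])))
        outlier["n_alleles"] = int(10 ** (np.log10(
            table["n_alleles"].iloc[0]) + 5 * sd))
        augmented = pd.concat([table, outlier], ignore_index=True)
        _, flagged2 = m.predict_and_flag(fit, augmented, seed=0)
        assert augmented.iloc[-1]["species"] in set(flagged2["species"])

    def test_species_at_predicted_mean_is_not_flagged(self, fitted_model):
        _, table, truth, cov, fit = fitted_model
        preds, _ = m.predict_and_flag(fit, table, seed=0)
        from mungomhc.comparative import IUCN_CODE
        synthetic = table.iloc[[0]].copy()
        status = IUCN_CODE[synthetic.iloc[0]["iucn_status"]]
        synthetic["n_alleles"] = max(1, int(round(
            10 ** preds.loc[status, "mean"])))
        augmented = pd.concat([table.iloc[1:], synthetic], ignore_index=True)
        _, flagged = m.predict_and_flag(fit, augmented, seed=0)
        y0 = np.log10(synthetic["n_alleles"].iloc[0])
        assert preds.loc[status, "pred_low"] <= y0 \
            <= preds.loc[status, "pred_high"]
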