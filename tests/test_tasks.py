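import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import pairlearn as pl
from pairlearn.io import RiskScoreTable, DiseaseTable
from pairlearn.tasks import (extract_embeddings, train_classifier, meta_outcome,
                             train_risk_head, evaluate_risk_head, cca_compare,
                             canonical_correlations, fused_svm_predict,
                             mlp_baseline, cluster_latents, weights_checksum)


@pytest.fixture(scope="module")
def emb(trained_bijection):
    t = trained_bijection
    return extract_embeddings(t["result"], t["gt"], t["pheno"])


class TestExtractEmbeddings:
    def test_deterministic(self, trained_bijection, emb):
        t = trained_bijection
        again = extract_embeddings(t["result"], t["gt"], t["pheno"])
        assert np.array_equal(emb.fused, again.fused)

    def test_fused_length(self, trained_bijection, emb):
        d = trained_bijection["result"].model.cfg.d_embed
        n_ent = len(emb.snp_ids) + len(emb.idp_ids)
        assert emb.fused.shape[1] == n_ent * d

    def test_identical_samples_identical_vectors(self, trained_bijection, emb):
        t = trained_bijection
        gt, pheno = t["gt"], t["pheno"]
        # find two samples with identical genotypes over vocab SNPs and
        # force identical phenotypes for them
        pv = pheno.values.copy()
        pv.iloc[1] = pv.iloc[0]
        gt2 = gt.subset()
        gt2.status[1] = gt2.status[0]
        gt2.dosage[1] = gt2.dosage[0]
        e = extract_embeddings(t["result"], gt2, pl.PhenotypeTable(pv))
        assert np.allclose(e.fused[0], e.fused[1])

    def test_changing_one_genotype_changes_only_that_block(self, trained_bijection):
        t = trained_bijection
        gt2 = t["gt"].subset()
        j = gt2.snp_ids.index(t["result"].tokenizer.snp_vocab.id_vocab.token_to_id[0])
        old = int(gt2.status[0, j])
        gt2.status[0, j] = 0 if old != 0 else 2
        gt2.dosage[0, j] = 0 if old != 0 else 2
        a = extract_embeddings(t["result"], t["gt"], t["pheno"], [t["gt"].sample_ids[0]])
        b = extract_embeddings(t["result"], gt2, t["pheno"], [gt2.sample_ids[0]])
        changed = [k for k in range(len(a.snp_ids))
                   if not np.allclose(a.snp_block[0, k], b.snp_block[0, k])]
        assert changed == [0]
        assert np.allclose(a.idp_block, b.idp_block)

    def test_unseen_sample_rejected(self, trained_bijection):
        t = trained_bijection
        with pytest.raises(KeyError):
            extract_embeddings(t["result"], t["gt"], t["pheno"], ["nope"])


class TestClassifier:
    def test_planted_disease_predictable(self, trained_bijection, emb):
        t = trained_bijection
        labels = t["dis"].indicator["disease_0"]
        res = train_classifier(emb, None, labels, epochs=40, seed=1)
        # oracle reference: logistic signal exists in raw dosages by design;
        # embeddings encode the same dosage information
        assert res.auc > 0.7

    def test_permuted_labels_near_chance(self, trained_bijection, emb):
        t = trained_bijection
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(5):
            y = t["dis"].indicator["disease_0"].sample(
                frac=1, random_state=rng.integers(2**31)).reset_index(drop=True)
            y.index = t["dis"].indicator.index
            aucs.append(train_classifier(emb, None, y, epochs=10, seed=2).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_deterministic_given_seed(self, trained_bijection, emb):
        t = trained_bijection
        labels = t["dis"].indicator["disease_0"]
        a = train_classifier(emb, None, labels, epochs=5, seed=3).auc
        b = train_classifier(emb, None, labels, epochs=5, seed=3).auc
        assert a == b

    def test_encoders_frozen_during_head_training(self, trained_bijection, emb):
        t = trained_bijection
        before = weights_checksum(t["result"].model)
        train_classifier(emb, None, t["dis"].indicator["disease_0"], epochs=3, seed=4)
        assert weights_checksum(t["result"].model) == before

    def test_single_class_rejected(self, trained_bijection, emb):
        t = trained_bijection
        y = pd.Series(0, index=t["dis"].indicator.index)
        with pytest.raises(ValueError):
            train_classifier(emb, None, y)


class TestMetaOutcome:
    def test_and_truth_table(self):
        dis = DiseaseTable(pd.DataFrame({"a": [1, 1, 0], "b": [1, 0, 0],
                                         "c": [1, 1, 1]}, index=list("xyz")))
        assert meta_outcome(dis).tolist() == [1, 0, 0]

    def test_or_mode(self):
        dis = DiseaseTable(pd.DataFrame({"a": [1, 0, 0], "b": [0, 0, 1]},
                                        index=list("xyz")))
        assert meta_outcome(dis, or_mode=True).tolist() == [1, 0, 1]

    def test_single_disease_identity(self):
        dis = DiseaseTable(pd.DataFrame({"a": [1, 0, 1]}, index=list("xyz")))
        assert meta_outcome(dis).tolist() == [1, 0, 1]

    def test_all_zero(self):
        dis = DiseaseTable(pd.DataFrame({"a": [0, 0], "b": [0, 0]}, index=list("xy")))
        assert meta_outcome(dis).tolist() == [0, 0]


class TestRiskHead:
    def test_realizable_linear_target(self, trained_bijection, emb):
        t = trained_bijection
        rng = np.random.default_rng(5)
        w = rng.normal(size=emb.fused.shape[1]) / np.sqrt(emb.fused.shape[1])
        y = emb.fused @ w
        scores = RiskScoreTable(pd.DataFrame(
            {"disease_0": y}, index=pd.Index(emb.sample_ids, name="sample_id")))
        res = train_risk_head(emb, scores, t["dis"], "disease_0",
                              dropout=0.0, lr=3e-3, epochs=150, seed=6)
        assert res.r2 > 0.9

    def test_pure_noise_target(self, trained_bijection, emb):
        t = trained_bijection
        rng = np.random.default_rng(7)
        scores = RiskScoreTable(pd.DataFrame(
            {"disease_0": rng.normal(size=len(emb.sample_ids))},
            index=pd.Index(emb.sample_ids, name="sample_id")))
        res = train_risk_head(emb, scores, t["dis"], "disease_0",
                              dropout=0.0, epochs=30, seed=8)
        assert res.r2 < 0.15

    def test_noiseless_dosage_score_recovered(self, trained_bijection, emb):
        """sigma = 0 risk scores are dosage-determined, and dosage is readable
        from the SNP embeddings, so the head can regress them accurately."""
        t = trained_bijection
        weights = {"disease_0": {v: w for v, w in zip(emb.snp_ids, [1.0, -0.5, 0.8, 0.3, -1.2,
                                                                     0.6, 0.9, -0.7, 0.2, 1.1])}}
        scores = pl.simulate_risk_scores(t["dis"], t["gt"], weights, sigma=0.0)
        res = train_risk_head(emb, scores, t["dis"], "disease_0",
                              dropout=0.0, lr=3e-3, epochs=150, seed=9)
        assert res.r2 > 0.9

    def test_cross_disorder_reuse(self, trained_bijection, emb):
        t = trained_bijection
        weights = {d: {emb.snp_ids[i]: 1.0} for i, d in
                   enumerate(["disease_0", "disease_1"])}
        scores = pl.simulate_risk_scores(t["dis"], t["gt"], weights, sigma=0.0)
        res = train_risk_head(emb, scores, t["dis"], "disease_0",
                              dropout=0.0, lr=3e-3, epochs=100, seed=10)
        r2_cross = evaluate_risk_head(res, emb, scores, t["dis"], "disease_1", seed=10)
        assert np.isfinite(r2_cross)
        # the reused head was trained on disease_0's target, so it should do
        # no better on disease_1 than on its own task
        assert r2_cross <= res.r2 + 0.05

    def test_too_few_cases_rejected(self, trained_bijection, emb):
        t = trained_bijection
        ind = t["dis"].indicator.copy()
        ind["rare"] = 0
        ind.iloc[0, -1] = 1
        scores = RiskScoreTable(pd.DataFrame(
            {"rare": np.zeros(len(emb.sample_ids))},
            index=pd.Index(emb.sample_ids, name="sample_id")))
        with pytest.raises(ValueError):
            train_risk_head(emb, scores, DiseaseTable(ind), "rare")


def cca_first_correlation_oracle(X, Y):
    """First canonical correlation via SVD of the whitened cross-covariance."""
    Xc = X - X.mean(0)
    Yc = Y - Y.mean(0)
    n = len(X)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    wx = np.linalg.inv(np.linalg.cholesky(Sxx))
    wy = np.linalg.inv(np.linalg.cholesky(Syy))
    M = wx @ Sxy @ wy.T
    return np.linalg.svd(M, compute_uv=False)[0]


class TestCca:
    def test_identical_views_first_correlation_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 5))
        cors = canonical_correlations(X, X.copy(), n_components=3)
        assert cors[0] == pytest.approx(1.0, abs=1e-8)

    def test_invertible_transform_all_ones(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        cors = canonical_correlations(X, X @ A, n_components=3)
        assert np.allclose(cors, 1.0, atol=1e-6)

    def test_independent_views_match_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(500, 5))
        Y = rng.normal(size=(500, 5))
        cors = canonical_correlations(X, Y, n_components=1, max_iter=20000, tol=1e-14)
        # standardize as canonical_correlations does before the oracle
        Xs = (X - X.mean(0)) / X.std(0)
        Ys = (Y - Y.mean(0)) / Y.std(0)
        assert cors[0] == pytest.approx(cca_first_correlation_oracle(Xs, Ys), abs=1e-8)

    def test_rank_deficiency_reduces_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        X = np.column_stack([X, X[:, 0]])  # rank 3 in 4 columns
        with pytest.warns(UserWarning, match="reducing"):
            cors = canonical_correlations(X, rng.normal(size=(50, 4)), n_components=4)
        assert len(cors) == 3

    def test_embedded_exceeds_raw_on_unseen_samples(self, trained_bijection):
        """Learned embeddings align the two modalities far beyond raw CCA."""
        t = trained_bijection
        sibling = pl.simulate_cohort(pl.planted_bijection_spec(
            n_samples=300, n_idps=5, beta=2.0, noise_sd=0.1, seed=303))
        gt_u, pheno_u, cov_u = sibling[0], sibling[1], sibling[2]
        e = extract_embeddings(t["result"], gt_u, pheno_u)
        snp_idx = [gt_u.snp_ids.index(v) for v in e.snp_ids]
        raw_snp = gt_u.dosage[:, snp_idx].astype(float)
        raw_idp = pheno_u.values[e.idp_ids].to_numpy()
        cov = cov_u.values[["age", "sex"]].to_numpy(float)
        out = cca_compare(raw_snp, raw_idp, e, covariates=cov, n_components=3)
        assert out["embedded"][0] > out["raw"][0]
        assert out["embedded"][0] > 0.95


class TestBaselines:
    def _data(self, trained_bijection):
        t = trained_bijection
        y = t["dis"].indicator["disease_0"].to_numpy()
        X_snp = t["gt"].dosage.astype(float)
        X_idp = t["pheno"].values.to_numpy()
        return X_snp, X_idp, y

    def test_fused_svm_planted_above_chance(self, trained_bijection):
        X_snp, X_idp, y = self._data(trained_bijection)
        auc = fused_svm_predict(X_snp, X_idp, y, seed=1)
        assert auc > 0.6

    def test_mlp_baseline_planted_above_chance(self, trained_bijection):
        X_snp, X_idp, y = self._data(trained_bijection)
        auc = mlp_baseline(X_snp, X_idp, y, epochs=40, seed=1)
        assert auc > 0.6

    def test_permuted_labels_near_chance(self, trained_bijection):
        X_snp, X_idp, y = self._data(trained_bijection)
        rng = np.random.default_rng(2)
        aucs = [mlp_baseline(X_snp, X_idp, rng.permutation(y), epochs=10, seed=3)
                for _ in range(4)]
        assert abs(np.mean(aucs) - 0.5) < 0.12

    def test_seeded_determinism(self, trained_bijection):
        X_snp, X_idp, y = self._data(trained_bijection)
        assert fused_svm_predict(X_snp, X_idp, y, seed=5) == \
            fused_svm_predict(X_snp, X_idp, y, seed=5)


class TestClusterLatents:
    def test_single_cluster(self, trained_bijection):
        t = trained_bijection
        out = cluster_latents(t["result"], t["gt"], t["pheno"], n_clusters=1,
                              reducer="pca", seed=0)
        assert (out["snp"]["cluster"] == 0).all()
        assert (out["idp"]["cluster"] == 0).all()

    def test_deterministic_labels(self, trained_bijection):
        t = trained_bijection
        a = cluster_latents(t["result"], t["gt"], t["pheno"], n_clusters=3,
                            reducer="pca", seed=1)
        b = cluster_latents(t["result"], t["gt"], t["pheno"], n_clusters=3,
                            reducer="pca", seed=1)
        pd.testing.assert_frame_equal(a["snp"], b["snp"])

    def test_too_many_clusters_rejected(self, trained_bijection):
        t = trained_bijection
        with pytest.raises(ValueError, match="fewer entities"):
            cluster_latents(t["result"], t["gt"], t["pheno"], n_clusters=99)

    def test_block_structure_recovered(self):
        """SNPs sharing a partner IDP cluster together in the latent space."""
        from pairlearn.simulate import (SimSpec, CatalogLink, IdpLink, TruePair)

        snps = [f"rs{j:04d}" for j in range(8)]
        idps = ["idp_A", "idp_B"]
        diseases = [f"d{j}" for j in range(8)]
        # two blocks of four SNPs, each SNP mediated to its block's IDP
        spec = SimSpec(
            n_samples=500, snp_ids=snps, idp_ids=idps, disease_ids=diseases,
            disease_prevalence={d: 0.3 for d in diseases},
            catalog_links=[CatalogLink(v, diseases[j], 1e-10)
                           for j, v in enumerate(snps)],
            idp_links=[IdpLink(idps[j // 4], diseases[j], 0.0) for j in range(8)],
            true_pairs=[TruePair(v, idps[j // 4], 2.0) for j, v in enumerate(snps)],
            maf={v: 0.3 for v in snps}, noise_sd=0.1, seed=21)
        gt, pheno, cov, dis, cat = pl.simulate_cohort(spec)
        cfg = pl.RunConfig(batch_size=32, max_epochs=12, warmup_steps=30,
                           n_bins=8, patience=12, seed=21)
        idp_map = pl.map_idps_to_diseases(pheno, dis, cov)
        records = pl.build_pairs(pl.select_top_snps(cat, 100), idp_map, gt.sample_ids)
        split = pl.split_pairs(records, seed=21)
        result = pl.train(split, gt, pheno, cfg)
        out = cluster_latents(result, gt, pheno, k_samples=5, n_clusters=2,
                              reducer="pca", seed=2)
        labels = out["snp"].set_index("entity_id").loc[snps, "cluster"].to_numpy()
        truth = np.array([0] * 4 + [1] * 4)
        assert adjusted_rand_score(truth, labels) > 0.8

    def test_umap_reducer_runs_seeded(self, trained_bijection):
        t = trained_bijection
        out = cluster_latents(t["result"], t["gt"], t["pheno"], n_clusters=2,
                              reducer="umap", seed=3)
        assert set(out) == {"snp", "idp"}
        assert len(out["snp"]) == 10 and len(out["idp"]) == 5
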