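"""Downstream use of the frozen learned embeddings.

Every task here consumes per-sample entity embeddings extracted from a
trained checkpoint in eval mode: for each SNP in the vocabulary the sample's
(SNP-ID, status) pair is encoded and projected, likewise each IDP with its
PLE vector, and the blocks are concatenated (SNP blocks in vocabulary order,
then IDP blocks) into one fused vector per sample.  The encoders are never
updated — only small heads are trained — so embedding extraction is
deterministic and the frozen-encoder guarantee is checkable by checksum.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.cross_decomposition import CCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from . import nn
from .io import DiseaseTable, GenotypeTable, PhenotypeTable, RiskScoreTable
from .model import TrainResult


# ---------------------------------------------------------------------------
# embeddings


@dataclass
class SampleEmbeddings:
    sample_ids: list[str]
    snp_ids: list[str]
    idp_ids: list[str]
    snp_block: np.ndarray  # (n_samples, n_snps, d)
    idp_block: np.ndarray  # (n_samples, n_idps, d)

    @property
    def fused(self) -> np.ndarray:
        n = len(self.sample_ids)
        return np.concatenate([self.snp_block.reshape(n, -1),
                               self.idp_block.reshape(n, -1)], axis=1)

    def fused_frame(self) -> pd.DataFrame:
        cols = [f"{v}_{k}" for v in self.snp_ids for k in range(self.snp_block.shape[2])]
        cols += [f"{p}_{k}" for p in self.idp_ids for k in range(self.idp_block.shape[2])]
        return pd.DataFrame(self.fused, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=cols)


def extract_embeddings(result: TrainResult, gt: GenotypeTable, pheno: PhenotypeTable,
                       sample_ids: list[str] | None = None) -> SampleEmbeddings:
    """Frozen per-sample entity embeddings in the joint space.

    Entities follow the checkpoint's vocabularies; a vocabulary SNP or IDP
    absent from the input tables is an error (no silent imputation).
    """
    model, tok = result.model, result.tokenizer
    if sample_ids is None:
        sample_ids = list(gt.sample_ids)
    sample_index = {s: i for i, s in enumerate(gt.sample_ids)}
    missing = [s for s in sample_ids if s not in sample_index]
    if missing:
        raise KeyError(f"samples absent from genotype table, e.g. {missing[:3]}")
    si = np.array([sample_index[s] for s in sample_ids])
    snp_ids = tok.snp_vocab.id_vocab.token_to_id
    idp_ids = tok.idp_vocab.token_to_id
    for v in snp_ids:
        if v not in gt.snp_ids:
            raise KeyError(f"checkpoint SNP {v!r} absent from genotype table")
    for p in idp_ids:
        if p not in pheno.values.columns:
            raise KeyError(f"checkpoint IDP {p!r} absent from phenotype table")
    snp_col = {v: j for j, v in enumerate(gt.snp_ids)}
    n, d = len(sample_ids), model.cfg.d_embed
    snp_block = np.empty((n, len(snp_ids), d))
    for t, v in enumerate(snp_ids):
        status = gt.status[si, snp_col[v]].astype(np.int64)
        id_tok = np.full(n, t, dtype=np.int64)
        snp_block[:, t, :] = model.project_snp(model.encode_snp(id_tok, status))
    idp_block = np.empty((n, len(idp_ids), d))
    pv = pheno.values.reindex(sample_ids)
    for t, p in enumerate(idp_ids):
        ple = tok.binner.encode_column(p, pv[p].to_numpy(), width=tok.n_bins)
        id_tok = np.full(n, t, dtype=np.int64)
        idp_block[:, t, :] = model.project_idp(model.encode_idp(id_tok, ple))
    return SampleEmbeddings(list(sample_ids), list(snp_ids), list(idp_ids),
                            snp_block, idp_block)


def weights_checksum(model) -> str:
    """Checksum of all model weights; guards the frozen-encoder contract."""
    h = hashlib.sha256()
    for k, p in sorted(model.params()):
        h.update(k.encode())
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# small head training on fixed features


def _standardize(train: np.ndarray, *others: np.ndarray):
    mu, sd = train.mean(axis=0), train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((a - mu) / sd for a in (train, *others))


def _fit_head(head: nn.MLPHead, X: np.ndarray, grad_fn, *, lr: float,
              epochs: int, batch_size: int, rng: np.random.Generator,
              weight_decay: float = 0.0) -> None:
    """Generic minibatch loop: grad_fn(logits, idx) -> (loss, dlogits)."""
    opt = nn.AdamW(head, lr=lr, weight_decay=weight_decay)
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if len(idx) < 2:
                continue
            head.zero_grad()
            z = head.forward(X[idx], train=True, rng=rng)
            _, dz = grad_fn(z, idx)
            head.backward(dz)
            opt.step()


def _bce_grad(z: np.ndarray, y: np.ndarray, w: np.ndarray):
    z = z[:, 0]
    loss = float(np.mean(w * (np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))))
    dz = (w * (expit(z) - y) / len(z))[:, None]
    return loss, dz


def _mse_grad(z: np.ndarray, y: np.ndarray):
    r = z[:, 0] - y
    return float(np.mean(r ** 2)), (2 * r / len(r))[:, None]


# ---------------------------------------------------------------------------
# disease classification


def meta_outcome(dis: DiseaseTable, or_mode: bool = False) -> pd.Series:
    """Combined outcome across all diseases: logical AND (OR optionally)."""
    ind = dis.indicator
    combined = ind.all(axis=1) if not or_mode else ind.any(axis=1)
    return combined.astype(int).rename("meta")


@dataclass
class ClassifierResult:
    head: nn.MLPHead
    auc: float
    predictions: pd.DataFrame  # sample_id, y_true, score, split


def train_classifier(emb: SampleEmbeddings, cov: pd.DataFrame | None,
                     labels: pd.Series, hidden: int = 64, dropout: float = 0.2,
                     lr: float = 1e-3, epochs: int = 30, batch_size: int = 64,
                     test_fraction: float = 0.2, seed: int = 7) -> ClassifierResult:
    """Binary disease classifier on frozen fused embeddings (+ covariates).

    Stratified sample split, inverse-class-frequency loss weights, one
    hidden-layer head; reports AUC on the held-out samples.
    """
    y = labels.reindex(emb.sample_ids).to_numpy(int)
    X = emb.fused
    if cov is not None:
        X = np.concatenate([X, cov.reindex(emb.sample_ids).to_numpy(float)], axis=1)
    if y.min() == y.max():
        raise ValueError("labels are single-class")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=y,
                              random_state=seed)
    if y[tr].sum() < 2 or (1 - y[tr]).sum() < 2:
        raise ValueError("need at least 2 cases and 2 controls in the train split")
    Xtr, Xte = _standardize(X[tr], X[te])
    w_class = len(tr) / (2.0 * np.bincount(y[tr], minlength=2))
    w = w_class[y[tr]]
    rng = np.random.default_rng(seed)
    head = nn.MLPHead(X.shape[1], hidden, 1, rng, dropout)
    _fit_head(head, Xtr, lambda z, i: _bce_grad(z, y[tr][i], w[i]),
              lr=lr, epochs=epochs, batch_size=batch_size, rng=rng)
    score_te = head.forward(Xte)[:, 0]
    auc = float(roc_auc_score(y[te], score_te))
    score_tr = head.forward(Xtr)[:, 0]
    pred = pd.DataFrame({
        "sample_id": [emb.sample_ids[i] for i in np.concatenate([tr, te])],
        "y_true": np.concatenate([y[tr], y[te]]),
        "score": np.concatenate([score_tr, score_te]),
        "split": ["train"] * len(tr) + ["test"] * len(te)})
    return ClassifierResult(head=head, auc=auc, predictions=pred)


# ---------------------------------------------------------------------------
# risk-score regression


@dataclass
class RiskSplit:
    train_samples: list[str]
    test_samples: list[str]


def risk_split(dis: DiseaseTable, disease_id: str, seed: int = 7) -> RiskSplit:
    """Cases plus an equal number of controls train; remaining controls test."""
    ind = dis.indicator[disease_id]
    cases = list(ind[ind == 1].index)
    controls = list(ind[ind == 0].index)
    if len(cases) < 2:
        raise ValueError(f"fewer than 2 cases for {disease_id!r}")
    if len(controls) <= len(cases):
        raise ValueError(f"not enough controls for {disease_id!r}")
    rng = np.random.default_rng(seed)
    picked = list(rng.choice(controls, size=len(cases), replace=False))
    rest = [c for c in controls if c not in set(picked)]
    return RiskSplit(train_samples=cases + picked, test_samples=rest)


@dataclass
class RiskResult:
    head: nn.MLPHead
    r2: float
    split: RiskSplit
    feature_stats: tuple[np.ndarray, np.ndarray]
    predictions: pd.DataFrame


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def train_risk_head(emb: SampleEmbeddings, scores: RiskScoreTable,
                    dis: DiseaseTable, disease_id: str, hidden: int = 64,
                    dropout: float = 0.2, lr: float = 1e-3, epochs: int = 50,
                    batch_size: int = 64, seed: int = 7) -> RiskResult:
    """Regress an external risk score from fused embeddings (MSE loss).

    The train split is the disease's cases plus an equal number of controls;
    evaluation is on the remaining, completely unseen controls and reports
    R^2 = 1 - SS_res / SS_tot (negative when worse than the mean).
    """
    split = risk_split(dis, disease_id, seed)
    index = {s: i for i, s in enumerate(emb.sample_ids)}
    tr = np.array([index[s] for s in split.train_samples])
    te = np.array([index[s] for s in split.test_samples])
    X = emb.fused
    y = scores.scores[disease_id].reindex(emb.sample_ids).to_numpy(float)
    mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
    # z-score the target for conditioning; predictions are mapped back
    y_mu, y_sd = y[tr].mean(), y[tr].std()
    y_sd = y_sd if y_sd > 0 else 1.0
    yz = (y - y_mu) / y_sd
    rng = np.random.default_rng(seed)
    head = nn.MLPHead(X.shape[1], hidden, 1, rng, dropout)
    _fit_head(head, Xtr, lambda z, i: _mse_grad(z, yz[tr][i]),
              lr=lr, epochs=epochs, batch_size=batch_size, rng=rng)
    yhat = head.forward(Xte)[:, 0] * y_sd + y_mu
    pred = pd.DataFrame({"sample_id": split.test_samples, "y_true": y[te], "y_pred": yhat})
    return RiskResult(head=head, r2=_r2(y[te], yhat), split=split,
                      feature_stats=(mu, sd), predictions=pred)


def evaluate_risk_head(result: RiskResult, emb: SampleEmbeddings,
                       scores: RiskScoreTable, dis: DiseaseTable,
                       disease_id: str, seed: int = 7) -> float:
    """Cross-disorder R^2: reuse a trained head verbatim on another disease's
    evaluation split (its remaining controls)."""
    split = risk_split(dis, disease_id, seed)
    index = {s: i for i, s in enumerate(emb.sample_ids)}
    te = np.array([index[s] for s in split.test_samples])
    mu, sd = result.feature_stats
    Xte = (emb.fused[te] - mu) / sd
    y = scores.scores[disease_id].reindex(emb.sample_ids).to_numpy(float)[te]
    return _r2(y, result.head.forward(Xte)[:, 0])


# ---------------------------------------------------------------------------
# CCA comparison and baselines


def _residualize(X: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    if C is None or C.size == 0:
        return X
    C1 = np.column_stack([np.ones(len(C)), C])
    beta, *_ = np.linalg.lstsq(C1, X, rcond=None)
    return X - C1 @ beta


def canonical_correlations(X: np.ndarray, Y: np.ndarray, n_components: int,
                           covariates: np.ndarray | None = None,
                           max_iter: int = 1000, tol: float = 1e-9) -> np.ndarray:
    """Canonical correlations of two standardized views after residualizing
    covariates out; components above the data rank are dropped with a warning."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    X = _residualize(X, covariates)
    Y = _residualize(Y, covariates)
    X, = _standardize(X)
    Y, = _standardize(Y)
    rank = min(np.linalg.matrix_rank(X), np.linalg.matrix_rank(Y), len(X) - 1)
    if n_components > rank:
        warnings.warn(f"reducing CCA components {n_components} -> {rank} (rank)")
        n_components = int(rank)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cca = CCA(n_components=n_components, max_iter=max_iter, tol=tol)
        U, V = cca.fit_transform(X, Y)
    cors = np.array([np.corrcoef(U[:, k], V[:, k])[0, 1] for k in range(n_components)])
    return cors


def cca_compare(raw_snp: np.ndarray, raw_idp: np.ndarray,
                emb: SampleEmbeddings, covariates: np.ndarray | None = None,
                n_components: int = 3) -> dict[str, np.ndarray]:
    """Canonical correlations of raw views vs vectorized learned embeddings.

    Both computations must be run on samples unseen by the contrastive
    trainer (the caller controls the sample set).
    """
    n = len(emb.sample_ids)
    raw = canonical_correlations(raw_snp, raw_idp, n_components, covariates)
    embd = canonical_correlations(emb.snp_block.reshape(n, -1),
                                  emb.idp_block.reshape(n, -1),
                                  n_components, covariates)
    return {"raw": raw, "embedded": embd}


def fused_svm_predict(X_snp: np.ndarray, X_idp: np.ndarray, y: np.ndarray,
                      n_components: int = 10, test_fraction: float = 0.2,
                      seed: int = 7) -> float:
    """CCA-SVM baseline: first canonical variates of both views fused, then a
    max-margin classifier; AUC on held-out samples (CCA fit on train only)."""
    if y.min() == y.max():
        raise ValueError("labels are single-class")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=y,
                              random_state=seed)
    Xs_tr, Xs_te = _standardize(X_snp[tr], X_snp[te])
    Xi_tr, Xi_te = _standardize(X_idp[tr], X_idp[te])
    rank = min(np.linalg.matrix_rank(Xs_tr), np.linalg.matrix_rank(Xi_tr))
    k = int(min(n_components, rank))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cca = CCA(n_components=k, max_iter=1000)
        cca.fit(Xs_tr, Xi_tr)
    F_tr = np.concatenate(cca.transform(Xs_tr, Xi_tr), axis=1)
    F_te = np.concatenate(cca.transform(Xs_te, Xi_te), axis=1)
    svm = SVC(kernel="rbf", class_weight="balanced", random_state=seed)
    svm.fit(F_tr, y[tr])
    return float(roc_auc_score(y[te], svm.decision_function(F_te)))


def mlp_baseline(X_snp: np.ndarray, X_idp: np.ndarray, y: np.ndarray,
                 hidden: int = 64, dropout: float = 0.2, lr: float = 1e-3,
                 epochs: int = 30, batch_size: int = 64,
                 test_fraction: float = 0.2, seed: int = 7) -> float:
    """Shallow MLP on concatenated raw dosages and IDPs; AUC on held-out."""
    if y.min() == y.max():
        raise ValueError("labels are single-class")
    X = np.concatenate([X_snp, X_idp], axis=1)
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=test_fraction, stratify=y,
                              random_state=seed)
    Xtr, Xte = _standardize(X[tr], X[te])
    w_class = len(tr) / (2.0 * np.bincount(y[tr], minlength=2))
    w = w_class[y[tr]]
    rng = np.random.default_rng(seed)
    head = nn.MLPHead(X.shape[1], hidden, 1, rng, dropout)
    _fit_head(head, Xtr, lambda z, i: _bce_grad(z, y[tr][i], w[i]),
              lr=lr, epochs=epochs, batch_size=batch_size, rng=rng)
    return float(roc_auc_score(y[te], head.forward(Xte)[:, 0]))


# ---------------------------------------------------------------------------
# latent-space clustering


def cluster_latents(result: TrainResult, gt: GenotypeTable, pheno: PhenotypeTable,
                    k_samples: int = 5, n_clusters: int = 8,
                    reducer: str = "umap", seed: int = 7) -> dict[str, pd.DataFrame]:
    """2-D map and cluster labels of the learned entity representations.

    For every SNP and IDP, k_samples randomly chosen samples are encoded;
    the point clouds are reduced to two dimensions (UMAP by default, PCA
    optionally) and clustered with K-means separately per modality.  Entity
    labels are the majority cluster of the entity's points.
    """
    from sklearn.cluster import KMeans

    rng = np.random.default_rng(seed)
    model, tok = result.model, result.tokenizer
    out = {}
    for modality in ("snp", "idp"):
        if modality == "snp":
            ids = tok.snp_vocab.id_vocab.token_to_id
            snp_col = {v: j for j, v in enumerate(gt.snp_ids)}
            points, owners = [], []
            for t, v in enumerate(ids):
                si = rng.choice(gt.n_samples, size=k_samples, replace=True)
                status = gt.status[si, snp_col[v]].astype(np.int64)
                e = model.project_snp(model.encode_snp(np.full(k_samples, t), status))
                points.append(e)
                owners += [t] * k_samples
        else:
            ids = tok.idp_vocab.token_to_id
            pv = pheno.values
            points, owners = [], []
            for t, p in enumerate(ids):
                si = rng.choice(len(pv), size=k_samples, replace=True)
                ple = tok.binner.encode_column(p, pv[p].to_numpy()[si], width=tok.n_bins)
                e = model.project_idp(model.encode_idp(np.full(k_samples, t), ple))
                points.append(e)
                owners += [t] * k_samples
        P = np.concatenate(points, axis=0)
        owners = np.array(owners)
        if len(ids) < n_clusters:
            raise ValueError(f"{modality}: fewer entities ({len(ids)}) than clusters")
        if reducer == "umap":
            import umap

            coords = umap.UMAP(n_components=2, random_state=seed,
                               n_neighbors=min(15, len(P) - 1)).fit_transform(P)
        elif reducer == "pca":
            from sklearn.decomposition import PCA

            coords = PCA(n_components=2, random_state=seed).fit_transform(P)
        else:
            raise ValueError(f"unknown reducer {reducer!r}")
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(coords)
        rows = []
        for t, ident in enumerate(ids):
            mask = owners == t
            labels, counts = np.unique(km.labels_[mask], return_counts=True)
            label = int(labels[np.argmax(counts)])
            x, y = coords[mask].mean(axis=0)
            rows.append((ident, x, y, label))
        out[modality] = pd.DataFrame(rows, columns=["entity_id", "x", "y", "cluster"])
    return out
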