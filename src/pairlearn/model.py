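"""CLIP-style contrastive learner over SNP and IDP tokens.

Two transformer encoders — one per modality — map each record's SNP token
pair and IDP encoding to feature vectors, which linear matrices project into
a joint space where rows are unit-normalized.  Within a batch of b records
the b x b matrix of scaled cosine similarities is scored with a symmetric
cross-entropy whose targets are the diagonal (each record's own partner).

Retrieval is reported on two scales:

* positional — the argmax of a row must be the diagonal entry itself.  With
  small token vocabularies a batch necessarily repeats SNP token pairs;
  repeated rows are identical and share one argmax, so positional accuracy
  is bounded above by E[#distinct SNP tokens in batch] / b for any model.
* identity-matched — the argmax column must carry the record's IDP identity.
  This is the scale on which "every pair retrieved correctly" is observable,
  and the headline pair-learning accuracy of the package.

Both are logged per record by :func:`evaluate`; the per-pair frequency
statistics consume the positional flags.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from . import nn
from .config import RunConfig
from .tokenize import PairTokenizer, TokenizedBatch

CLIP_INIT_LOGIT_SCALE = math.log(1.0 / 0.07)
MAX_LOGIT_SCALE = math.log(100.0)


@dataclass
class EncoderConfig:
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 64
    d_embed: int = 32
    dropout: float = 0.0
    temperature_mode: str = "learnable"

    @classmethod
    def from_run_config(cls, cfg: RunConfig) -> "EncoderConfig":
        return cls(d_model=cfg.d_model, n_layers=cfg.n_layers, n_heads=cfg.n_heads,
                   d_ff=cfg.d_ff, d_embed=cfg.d_embed, dropout=cfg.dropout,
                   temperature_mode=cfg.temperature_mode)


# ---------------------------------------------------------------------------
# loss and retrieval on a similarity matrix


def _log_softmax(x: np.ndarray, axis: int) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def contrastive_loss(sim: np.ndarray) -> float:
    """Symmetric cross-entropy of a square scaled-similarity matrix.

    Average of the row-wise (SNP -> IDP) and column-wise (IDP -> SNP)
    cross-entropies with diagonal targets; ln(b) for an all-equal matrix.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {sim.shape}")
    b = sim.shape[0]
    if b < 2:
        raise ValueError("need at least 2 pairs for a contrastive batch")
    diag = np.arange(b)
    loss_rows = -_log_softmax(sim, axis=1)[diag, diag].mean()
    loss_cols = -_log_softmax(sim, axis=0)[diag, diag].mean()
    return float(0.5 * (loss_rows + loss_cols))


def contrastive_loss_grad(sim: np.ndarray) -> np.ndarray:
    """Gradient of :func:`contrastive_loss` with respect to the matrix entries."""
    sim = np.asarray(sim, dtype=float)
    b = sim.shape[0]
    eye = np.eye(b)
    p_rows = np.exp(_log_softmax(sim, axis=1))
    p_cols = np.exp(_log_softmax(sim, axis=0))
    return 0.5 * ((p_rows - eye) + (p_cols - eye)) / b


def retrieval_accuracy(sim: np.ndarray) -> float:
    """Fraction of rows whose argmax is the diagonal (SNP -> IDP direction).

    Ties break toward the lowest column index and count as correct only when
    that index is the diagonal.
    """
    sim = np.asarray(sim)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {sim.shape}")
    b = sim.shape[0]
    return float((sim.argmax(axis=1) == np.arange(b)).mean())


# ---------------------------------------------------------------------------
# dual encoder


class DualEncoder(nn.Module):
    """Transformer encoders for SNP token pairs and IDP encodings.

    The SNP branch concatenates a SNP-ID embedding (d_model/2, acting as a
    positional encoding for genomic identity) with a mutation-status
    embedding (d_model/2); the IDP branch concatenates an IDP-ID embedding
    with a linear map of the PLE vector.  Each concatenation passes through
    its own encoder stack and is projected by a weight matrix into the joint
    d_embed space, where rows are unit-normalized.
    """

    def __init__(self, n_snps: int, n_status: int, n_idps: int, n_bins: int,
                 cfg: EncoderConfig, seed=0):
        rng = np.random.default_rng(seed)  # int or SeedSequence
        d_half = cfg.d_model // 2
        self.cfg = cfg
        self.n_bins = n_bins
        self.snp_id_embed = nn.Embedding(n_snps, d_half, rng)
        self.snp_status_embed = nn.Embedding(n_status, d_half, rng)
        self.idp_id_embed = nn.Embedding(n_idps, d_half, rng)
        self.ple_proj = nn.Linear(n_bins, d_half, rng)
        self.snp_encoder = nn.TransformerEncoder(
            cfg.d_model, cfg.n_layers, cfg.n_heads, cfg.d_ff, rng, cfg.dropout)
        self.idp_encoder = nn.TransformerEncoder(
            cfg.d_model, cfg.n_layers, cfg.n_heads, cfg.d_ff, rng, cfg.dropout)
        self.w_snp = nn.Param(nn._glorot(rng, cfg.d_model, cfg.d_embed), decay=True)
        self.w_idp = nn.Param(nn._glorot(rng, cfg.d_model, cfg.d_embed), decay=True)
        init_scale = CLIP_INIT_LOGIT_SCALE if cfg.temperature_mode == "learnable" else 0.0
        self.logit_scale = nn.Param(np.array(init_scale), decay=False)

    # -- forward pieces -----------------------------------------------------

    def encode_snp(self, id_tokens: np.ndarray, status_tokens: np.ndarray,
                   train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Raw SNP features S_f, shape (b, d_model)."""
        x = np.concatenate([self.snp_id_embed.forward(id_tokens),
                            self.snp_status_embed.forward(status_tokens)], axis=-1)
        h = self.snp_encoder.forward(x[:, None, :], train, rng)
        return h[:, 0, :]

    def encode_idp(self, id_tokens: np.ndarray, ple: np.ndarray,
                   train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Raw IDP features I_f, shape (b, d_model)."""
        x = np.concatenate([self.idp_id_embed.forward(id_tokens),
                            self.ple_proj.forward(ple)], axis=-1)
        h = self.idp_encoder.forward(x[:, None, :], train, rng)
        return h[:, 0, :]

    def project_snp(self, s_f: np.ndarray) -> np.ndarray:
        e, _ = nn.l2_normalize(s_f @ self.w_snp.value)
        return e

    def project_idp(self, i_f: np.ndarray) -> np.ndarray:
        e, _ = nn.l2_normalize(i_f @ self.w_idp.value)
        return e

    def similarity(self, batch: TokenizedBatch) -> np.ndarray:
        """Scaled cosine-similarity matrix for a tokenized batch (eval mode)."""
        s_e = self.project_snp(self.encode_snp(batch.snp_id_tokens, batch.snp_status_tokens))
        i_e = self.project_idp(self.encode_idp(batch.idp_id_tokens, batch.idp_ple))
        return (s_e @ i_e.T) * math.exp(float(self.logit_scale.value))

    # -- one training step --------------------------------------------------

    def loss_and_backward(self, batch: TokenizedBatch,
                          rng: np.random.Generator | None = None) -> float:
        """Forward + full backward pass for one batch; returns the loss."""
        b = len(batch)
        s_f = self.encode_snp(batch.snp_id_tokens, batch.snp_status_tokens, True, rng)
        i_f = self.encode_idp(batch.idp_id_tokens, batch.idp_ple, True, rng)
        s_p = s_f @ self.w_snp.value
        i_p = i_f @ self.w_idp.value
        s_e, s_n = nn.l2_normalize(s_p)
        i_e, i_n = nn.l2_normalize(i_p)
        scale = math.exp(float(self.logit_scale.value))
        cos = s_e @ i_e.T
        logits = cos * scale
        loss = contrastive_loss(logits)

        dlogits = contrastive_loss_grad(logits)
        if self.cfg.temperature_mode == "learnable":
            self.logit_scale.grad += (dlogits * cos).sum() * scale
        ds_e = dlogits @ i_e * scale
        di_e = dlogits.T @ s_e * scale
        ds_p = nn.l2_normalize_backward(ds_e, s_e, s_n)
        di_p = nn.l2_normalize_backward(di_e, i_e, i_n)
        self.w_snp.grad += s_f.T @ ds_p
        self.w_idp.grad += i_f.T @ di_p
        ds_f = ds_p @ self.w_snp.value.T
        di_f = di_p @ self.w_idp.value.T
        dx_s = self.snp_encoder.backward(ds_f[:, None, :])[:, 0, :]
        dx_i = self.idp_encoder.backward(di_f[:, None, :])[:, 0, :]
        d_half = self.cfg.d_model // 2
        self.snp_id_embed.backward(dx_s[:, :d_half])
        self.snp_status_embed.backward(dx_s[:, d_half:])
        self.idp_id_embed.backward(dx_i[:, :d_half])
        self.ple_proj.backward(dx_i[:, d_half:])
        return loss

    def post_step(self) -> None:
        # keep the learnable temperature in CLIP's stable range
        np.clip(self.logit_scale.value, -MAX_LOGIT_SCALE, MAX_LOGIT_SCALE,
                out=self.logit_scale.value)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainState:
    best_epoch: int = -1
    best_val_accuracy: float = -1.0
    best_weights: dict | None = None
    seed: int = 0
    history: list[dict] = field(default_factory=list)


@dataclass
class TrainResult:
    model: DualEncoder
    tokenizer: PairTokenizer
    state: TrainState
    config: RunConfig


def iter_batches(n: int, batch_size: int,
                 rng: np.random.Generator | None = None) -> Iterator[np.ndarray]:
    """Yield index batches; a trailing fragment of fewer than 2 is dropped."""
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        if len(idx) >= 2:
            yield idx


def _accuracy_over_batches(model: DualEncoder, tokens: TokenizedBatch,
                           batch_size: int) -> tuple[float, float]:
    """(positional, identity-matched) retrieval accuracy over fixed batches."""
    n_pos = n_id = n_tot = 0
    for idx in iter_batches(len(tokens), batch_size):
        tb = tokens.take(idx)
        sim = model.similarity(tb)
        arg = sim.argmax(axis=1)
        diag = np.arange(len(tb))
        n_pos += int((arg == diag).sum())
        n_id += int((tb.idp_id_tokens[arg] == tb.idp_id_tokens).sum())
        n_tot += len(tb)
    if n_tot == 0:
        return 0.0, 0.0
    return n_pos / n_tot, n_id / n_tot


def train(split, gt, pheno, cfg: RunConfig,
          tokenizer: PairTokenizer | None = None,
          selection: str = "positional",
          callback: Callable[[dict], None] | None = None) -> TrainResult:
    """Train the dual encoder on a pair split.

    Per epoch: shuffle the training records with a seeded generator, iterate
    batches with linear warmup then constant learning rate and decoupled
    weight decay, then score validation retrieval accuracy; the best
    validation epoch's weights are kept.  Fully reproducible from cfg.seed on
    a single device.
    """
    if selection not in ("positional", "identity"):
        raise ValueError(f"unknown selection metric {selection!r}")
    if tokenizer is None:
        tokenizer = PairTokenizer.fit(gt, pheno, split.train, cfg.n_bins)
    root = np.random.SeedSequence(cfg.seed)
    ss_init, ss_shuffle, ss_drop = root.spawn(3)
    model = DualEncoder(len(tokenizer.snp_vocab), tokenizer.snp_vocab.n_status,
                        len(tokenizer.idp_vocab), tokenizer.n_bins,
                        EncoderConfig.from_run_config(cfg), seed=ss_init)
    shuffle_rng = np.random.default_rng(ss_shuffle)
    drop_rng = np.random.default_rng(ss_drop)
    opt = nn.AdamW(model, lr=cfg.learning_rate,
                   warmup_steps=cfg.warmup_steps, weight_decay=cfg.weight_decay)

    train_tokens = tokenizer.encode_records(split.train, gt, pheno)
    val_tokens = tokenizer.encode_records(split.val, gt, pheno)
    val_batch = cfg.val_batch_size or cfg.batch_size
    state = TrainState(seed=cfg.seed)
    since_best = 0
    for epoch in range(cfg.max_epochs):
        losses = []
        for bi, idx in enumerate(iter_batches(len(train_tokens), cfg.batch_size,
                                              shuffle_rng)):
            model.zero_grad()
            loss = model.loss_and_backward(train_tokens.take(idx), drop_rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi}, "
                    f"lr {opt.current_lr():.3g}")
            opt.step()
            model.post_step()
            losses.append(loss)
        val_pos, val_id = _accuracy_over_batches(model, val_tokens, val_batch)
        score = val_pos if selection == "positional" else val_id
        record = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                  "val_accuracy": val_pos, "val_accuracy_identity": val_id,
                  "lr": opt.current_lr()}
        state.history.append(record)
        if callback is not None:
            callback(record)
        if score > state.best_val_accuracy:
            state.best_val_accuracy = score
            state.best_epoch = epoch
            state.best_weights = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if state.best_weights is not None:
        model.load_state_dict(state.best_weights)
    return TrainResult(model=model, tokenizer=tokenizer, state=state, config=cfg)


# ---------------------------------------------------------------------------
# evaluation log


def evaluate(model: DualEncoder, tokenizer: PairTokenizer, records: pd.DataFrame,
             gt, pheno, batch_size: int = 64) -> pd.DataFrame:
    """Per-record retrieval log over test batches.

    For each batch and position, records the pair identifiers, whether the
    row argmax hit the diagonal (positional) and whether the retrieved column
    carries the record's IDP identity.  A trailing fragment of fewer than 2
    records is dropped (no contrast is defined for it).
    """
    tokens = tokenizer.encode_records(records, gt, pheno)
    idp_ids = np.asarray(records["idp_id"])
    snp_ids = np.asarray(records["snp_id"])
    rows = []
    for batch_no, idx in enumerate(iter_batches(len(tokens), batch_size)):
        tb = tokens.take(idx)
        sim = model.similarity(tb)
        arg = sim.argmax(axis=1)
        diag = np.arange(len(tb))
        for pos in range(len(tb)):
            rows.append((batch_no, idp_ids[idx[pos]], snp_ids[idx[pos]],
                         bool(arg[pos] == diag[pos]),
                         idp_ids[idx[arg[pos]]],
                         bool(tb.idp_id_tokens[arg[pos]] == tb.idp_id_tokens[pos])))
    return pd.DataFrame(rows, columns=["batch", "idp_id", "snp_id", "correct",
                                       "retrieved_idp_id", "correct_identity"])


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(path: str | Path, result: TrainResult) -> None:
    """One self-describing archive: weights + vocabularies + binner + config."""
    import dataclasses

    path = Path(path)
    meta = {
        "config": {**dataclasses.asdict(result.config),
                   "split_fractions": list(result.config.split_fractions)},
        "tokenizer": {
            "snp_vocab": result.tokenizer.snp_vocab.to_dict(),
            "idp_ids": result.tokenizer.idp_vocab.token_to_id,
            "boundaries": {k: list(v) for k, v in result.tokenizer.binner.boundaries.items()},
            "train_means": result.tokenizer.binner.train_means,
        },
        "best_epoch": result.state.best_epoch,
        "best_val_accuracy": result.state.best_val_accuracy,
        "seed": result.state.seed,
    }
    weights = {f"w::{k}": v for k, v in result.model.state_dict().items()}
    np.savez(path, meta=json.dumps(meta), **weights)


def load_checkpoint(path: str | Path) -> TrainResult:
    from .tokenize import PleBinner, SnpVocab, Vocab

    data = np.load(Path(path), allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg_d = meta["config"]
    cfg_d["split_fractions"] = tuple(cfg_d["split_fractions"])
    cfg = RunConfig(**cfg_d)
    tok_meta = meta["tokenizer"]
    tokenizer = PairTokenizer(
        SnpVocab.from_dict(tok_meta["snp_vocab"]), Vocab(tok_meta["idp_ids"]),
        PleBinner(tok_meta["boundaries"], tok_meta["train_means"]))
    model = DualEncoder(len(tokenizer.snp_vocab), tokenizer.snp_vocab.n_status,
                        len(tokenizer.idp_vocab), tokenizer.n_bins,
                        EncoderConfig.from_run_config(cfg))
    model.load_state_dict({k[3:]: data[k] for k in data.files if k.startswith("w::")})
    state = TrainState(best_epoch=meta["best_epoch"],
                       best_val_accuracy=meta["best_val_accuracy"], seed=meta["seed"])
    return TrainResult(model=model, tokenizer=tokenizer, state=state, config=cfg)
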