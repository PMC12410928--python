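"""Tokenization: piecewise linear encodings for IDPs, token pairs for SNPs.

An IDP value is encoded *relative to the rest* of the training distribution:
bin boundaries are empirical quantiles of the training split, and the
encoding is a prefix of ones up to the bin holding the value, one fractional
interpolated entry, zeros after — so the vector lives in [0, 1]^T and is
componentwise monotone in the value.  A SNP is a pair of integer tokens:
its identifier (acting as a positional/location encoding) and its mutation
status drawn from the six-code alphabet.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import STATUS_CODES, STATUS_TO_INT, GenotypeTable, PhenotypeTable


class ConstantIdpError(ValueError):
    pass


class PleBinner:
    """Per-IDP quantile bin boundaries fit on the training split only."""

    def __init__(self, boundaries: Mapping[str, np.ndarray],
                 train_means: Mapping[str, float]):
        self.boundaries = {k: np.asarray(v, dtype=float) for k, v in boundaries.items()}
        self.train_means = dict(train_means)
        for idp, b in self.boundaries.items():
            if len(b) < 2 or not np.all(np.diff(b) > 0):
                raise ValueError(f"boundaries for {idp!r} must be strictly increasing")

    @classmethod
    def fit(cls, values: pd.DataFrame, n_bins: int = 10) -> "PleBinner":
        """Fit boundaries at quantiles 0, 1/T, ..., 1 of each IDP's values.

        Missing values are mean-imputed before fitting.  Duplicate quantiles
        (heavy ties) are collapsed with a warning, reducing that IDP's
        effective bin count.
        """
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        boundaries, means = {}, {}
        for idp in values.columns:
            x = values[idp].to_numpy(float)
            mean = float(np.nanmean(x)) if np.isnan(x).any() else float(x.mean())
            x = np.where(np.isnan(x), mean, x)
            if np.unique(x).size < 2:
                raise ConstantIdpError(f"IDP {idp!r} is constant on the training split")
            qs = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
            b = np.unique(qs)
            if len(b) < n_bins + 1:
                warnings.warn(
                    f"IDP {idp!r}: duplicate quantile boundaries collapsed, "
                    f"effective bins {len(b) - 1} < {n_bins}")
            boundaries[idp] = b
            means[idp] = mean
        return cls(boundaries, means)

    def n_bins(self, idp_id: str) -> int:
        return len(self.boundaries[idp_id]) - 1

    @property
    def max_bins(self) -> int:
        return max(len(b) - 1 for b in self.boundaries.values())

    def encode(self, idp_id: str, x: float) -> np.ndarray:
        """Piecewise linear encoding of a single value."""
        if not np.isfinite(x):
            raise ValueError(f"non-finite value {x!r} for IDP {idp_id!r}")
        b = self.boundaries[idp_id]
        return np.clip((x - b[:-1]) / np.diff(b), 0.0, 1.0)

    def encode_column(self, idp_id: str, x: np.ndarray, width: int | None = None) -> np.ndarray:
        """Vectorized encoding; NaNs take the training mean; optional zero padding."""
        b = self.boundaries[idp_id]
        x = np.asarray(x, dtype=float)
        x = np.where(np.isnan(x), self.train_means[idp_id], x)
        if not np.isfinite(x).all():
            raise ValueError(f"non-finite value for IDP {idp_id!r}")
        enc = np.clip((x[:, None] - b[:-1]) / np.diff(b), 0.0, 1.0)
        if width is not None and enc.shape[1] < width:
            enc = np.pad(enc, ((0, 0), (0, width - enc.shape[1])))
        return enc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "boundaries": {k: list(v) for k, v in self.boundaries.items()},
            "train_means": self.train_means}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PleBinner":
        d = json.loads(Path(path).read_text())
        return cls(d["boundaries"], d["train_means"])


class Vocab:
    """Injective id -> integer token mapping; frozen vocabs reject unseen ids."""

    def __init__(self, ids: Sequence[str], frozen: bool = True):
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in vocabulary")
        self.id_to_token = {s: i for i, s in enumerate(ids)}
        self.token_to_id = list(ids)
        self.frozen = frozen

    def __len__(self) -> int:
        return len(self.token_to_id)

    def encode(self, ident: str) -> int:
        try:
            return self.id_to_token[ident]
        except KeyError:
            raise KeyError(f"unseen id {ident!r} on frozen vocabulary") from None

    def decode(self, token: int) -> str:
        return self.token_to_id[token]

    def encode_many(self, idents: Sequence[str]) -> np.ndarray:
        return np.array([self.encode(s) for s in idents], dtype=np.int64)


@dataclass
class SnpVocab:
    """SNP-ID vocabulary plus the fixed mutation-status vocabulary."""

    id_vocab: Vocab
    status_vocab: Mapping[str, int] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.status_vocab is None:
            self.status_vocab = dict(STATUS_TO_INT)

    @classmethod
    def from_ids(cls, snp_ids: Sequence[str]) -> "SnpVocab":
        return cls(Vocab(sorted(snp_ids)))

    def __len__(self) -> int:
        return len(self.id_vocab)

    @property
    def n_status(self) -> int:
        return len(self.status_vocab)

    def tokenize(self, snp_id: str, status: str | int) -> tuple[int, int]:
        """(id token, status token) for one genotype call."""
        if isinstance(status, (int, np.integer)):
            status = STATUS_CODES[int(status)]
        if status not in self.status_vocab:
            raise KeyError(f"unknown mutation status {status!r}")
        return self.id_vocab.encode(snp_id), self.status_vocab[status]

    def to_dict(self) -> dict:
        return {"snp_ids": self.id_vocab.token_to_id,
                "status": dict(self.status_vocab)}

    @classmethod
    def from_dict(cls, d: dict) -> "SnpVocab":
        return cls(Vocab(d["snp_ids"]), d["status"])


def tokenize_snp(snp_id: str, status: str | int, vocab: SnpVocab) -> tuple[int, int]:
    return vocab.tokenize(snp_id, status)


def fit_ple(values: pd.DataFrame, n_bins: int = 10) -> PleBinner:
    return PleBinner.fit(values, n_bins)


def encode_ple(x: float, binner: PleBinner, idp_id: str | None = None) -> np.ndarray:
    if idp_id is None:
        if len(binner.boundaries) != 1:
            raise ValueError("idp_id required for a multi-IDP binner")
        idp_id = next(iter(binner.boundaries))
    return binner.encode(idp_id, x)


@dataclass
class TokenizedBatch:
    """Aligned token arrays for b pair records."""

    snp_id_tokens: np.ndarray    # (b,)
    snp_status_tokens: np.ndarray  # (b,)
    idp_id_tokens: np.ndarray    # (b,)
    idp_ple: np.ndarray          # (b, T)

    def __post_init__(self) -> None:
        b = len(self.snp_id_tokens)
        if not (len(self.snp_status_tokens) == len(self.idp_id_tokens)
                == self.idp_ple.shape[0] == b):
            raise ValueError("token arrays must align on the same records")

    def __len__(self) -> int:
        return len(self.snp_id_tokens)

    def take(self, idx: np.ndarray) -> "TokenizedBatch":
        return TokenizedBatch(self.snp_id_tokens[idx], self.snp_status_tokens[idx],
                              self.idp_id_tokens[idx], self.idp_ple[idx])


class PairTokenizer:
    """Turns pair records plus raw tables into aligned token arrays.

    Vocabularies and the PLE binner are fit once (binner on the training
    split only) and frozen; encoding validation or test records never touches
    the binner's boundaries.
    """

    def __init__(self, snp_vocab: SnpVocab, idp_vocab: Vocab, binner: PleBinner):
        self.snp_vocab = snp_vocab
        self.idp_vocab = idp_vocab
        self.binner = binner

    @classmethod
    def fit(cls, gt: GenotypeTable, pheno: PhenotypeTable,
            train_records: pd.DataFrame, n_bins: int = 10) -> "PairTokenizer":
        snp_ids = sorted(train_records["snp_id"].unique())
        idp_ids = sorted(train_records["idp_id"].unique())
        train_samples = train_records["sample_id"].unique()
        train_values = pheno.values.loc[
            pheno.values.index.intersection(train_samples), idp_ids]
        binner = PleBinner.fit(train_values, n_bins)
        return cls(SnpVocab.from_ids(snp_ids), Vocab(idp_ids), binner)

    @property
    def n_bins(self) -> int:
        return self.binner.max_bins

    def encode_records(self, records: pd.DataFrame, gt: GenotypeTable,
                       pheno: PhenotypeTable) -> TokenizedBatch:
        sample_index = {s: i for i, s in enumerate(gt.sample_ids)}
        snp_index = {v: j for j, v in enumerate(gt.snp_ids)}
        si = np.array([sample_index[s] for s in records["sample_id"]])
        vj = np.array([snp_index[v] for v in records["snp_id"]])
        snp_id_tok = self.snp_vocab.id_vocab.encode_many(records["snp_id"])
        status_tok = gt.status[si, vj].astype(np.int64)
        idp_id_tok = self.idp_vocab.encode_many(records["idp_id"])
        # precompute the PLE matrix per (sample, idp) once, then gather
        T = self.n_bins
        idp_ids = self.idp_vocab.token_to_id
        ple_all = np.zeros((gt.n_samples, len(idp_ids), T))
        pv = pheno.values.reindex(gt.sample_ids)
        for k, idp in enumerate(idp_ids):
            ple_all[:, k, :] = self.binner.encode_column(idp, pv[idp].to_numpy(), width=T)
        ple = ple_all[si, idp_id_tok]
        return TokenizedBatch(snp_id_tok, status_tok, idp_id_tok, ple)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "snp_vocab": self.snp_vocab.to_dict(),
            "idp_ids": self.idp_vocab.token_to_id,
            "boundaries": {k: list(v) for k, v in self.binner.boundaries.items()},
            "train_means": self.binner.train_means}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PairTokenizer":
        d = json.loads(Path(path).read_text())
        return cls(SnpVocab.from_dict(d["snp_vocab"]), Vocab(d["idp_ids"]),
                   PleBinner(d["boundaries"], d["train_means"]))
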