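"""Run configuration: every tunable of the pipeline in one serializable object.

Model defaults follow the tuned configuration of the method (2 transformer
layers, 64-wide, 4 heads, feed-forward width 64, learning rate 3.3e-3 with 236
linear warmup steps and decoupled weight decay 1.5e-3).  Genotype QC defaults
are the standard thresholds: sample missingness 10%, MAF 5%, HWE p 1e-16.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # genotype QC
    sample_missing_max: float = 0.10
    snp_missing_max: float = 0.05
    maf_min: float = 0.05
    hwe_p_min: float = 1e-16
    # pair making
    top_snp_percent: float = 100.0
    phewas_alpha: float = 0.05  # family-wise level, Bonferroni-divided per test
    split_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    split_mode: str = "by_pair"  # or "by_sample"
    # tokenization
    n_bins: int = 10
    # model (dual encoder)
    d_model: int = 64
    n_layers: int = 2
    n_heads: int = 4
    d_ff: int = 64
    d_embed: int = 32
    dropout: float = 0.0
    temperature_mode: str = "learnable"  # or "fixed"
    # optimization
    batch_size: int = 64
    val_batch_size: int | None = None  # validation retrieval batch; defaults to batch_size
    learning_rate: float = 0.0033
    warmup_steps: int = 236
    weight_decay: float = 0.0015
    max_epochs: int = 50
    patience: int = 10
    # misc
    seed: int = 7
    chi2_correction: str = "global"  # or "per_pair"
    p_adjust: str = "bh"  # or "bonferroni"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        f = self.split_fractions
        if len(f) != 3 or abs(sum(f) - 1.0) > 1e-9 or any(x <= 0 for x in f):
            raise ValueError(f"split fractions must be positive and sum to 1, got {f}")
        for name, lo, hi in [
            ("sample_missing_max", 0.0, 1.0),
            ("snp_missing_max", 0.0, 1.0),
            ("maf_min", 0.0, 0.5),
            ("hwe_p_min", 0.0, 1.0),
            ("dropout", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if not (0 < self.top_snp_percent <= 100):
            raise ValueError("top_snp_percent must be in (0, 100]")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 for in-batch contrastive learning")
        if self.split_mode not in ("by_pair", "by_sample"):
            raise ValueError(f"unknown split_mode {self.split_mode!r}")
        if self.temperature_mode not in ("learnable", "fixed"):
            raise ValueError(f"unknown temperature_mode {self.temperature_mode!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)
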