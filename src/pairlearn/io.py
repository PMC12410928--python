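"""Tables, file formats and genotype quality control.

Genotypes are held as a dense sample x SNP matrix of categorical mutation
statuses (hom_ref / het / hom_alt / insertion / deletion / missing) together
with the alt-allele dosage in {0, 1, 2}.  Two on-disk dialects are supported:
VCF (GT field only, read through cyvcf2) and a plain TSV with columns
``sample_id, snp_id, ref, alt, genotype`` so that simulated cohorts never need
a VCF writer.  Phenotypes, covariates, disease indicators and risk scores are
CSV; the SNP-disease catalog and all result tables are TSV.

QC follows standard genotype practice: samples with more than 10% missing
calls are dropped first, then SNPs are dropped for missingness, minor allele
frequency below 0.05, or Hardy-Weinberg disequilibrium at p < 1e-16 (exact
test for fewer than 1000 genotyped samples, 1-df chi-square otherwise).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

# ---------------------------------------------------------------------------
# mutation-status alphabet

STATUS_CODES = ("hom_ref", "het", "hom_alt", "insertion", "deletion", "missing")
STATUS_TO_INT = {s: i for i, s in enumerate(STATUS_CODES)}
HOM_REF, HET, HOM_ALT, INSERTION, DELETION, MISSING = range(6)

MISSING_DOSAGE = -1  # sentinel in the int8 dosage matrix


class FormatError(ValueError):
    """A file parsed but violated the dialect's contract."""


class AlignmentError(ValueError):
    """Sample identifiers cannot be aligned across modalities."""


def status_from_genotype(ref: str, alt: str, a1: int, a2: int) -> tuple[int, int]:
    """Map one genotype call to (status code, dosage).

    Alleles are 0 (ref) / 1 (alt) / -1 (uncalled).  Any call carrying an alt
    allele at an indel site is coded insertion/deletion (length of alt vs ref);
    SNV sites code het / hom_alt by alt count.
    """
    if a1 < 0 or a2 < 0:
        return MISSING, MISSING_DOSAGE
    dosage = a1 + a2
    if dosage == 0:
        return HOM_REF, 0
    if len(alt) > len(ref):
        return INSERTION, dosage
    if len(alt) < len(ref):
        return DELETION, dosage
    return (HET if dosage == 1 else HOM_ALT), dosage


# ---------------------------------------------------------------------------
# domain tables


@dataclass
class GenotypeTable:
    """Per-sample categorical mutation status per SNP with allele context."""

    sample_ids: list[str]
    snp_ids: list[str]
    ref_allele: np.ndarray  # (n_snps,) str
    alt_allele: np.ndarray  # (n_snps,) str
    status: np.ndarray      # (n_samples, n_snps) int8, codes above
    dosage: np.ndarray      # (n_samples, n_snps) int8, -1 == missing

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.status.shape != (n, m) or self.dosage.shape != (n, m):
            raise ValueError("status/dosage shape mismatch with ids")
        if len(set(self.snp_ids)) != m:
            raise FormatError("duplicate snp_id in genotype table")
        if ((self.status == MISSING) != (self.dosage == MISSING_DOSAGE)).any():
            raise ValueError("dosage must be missing iff status is missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, sample_idx: np.ndarray | None = None,
               snp_idx: np.ndarray | None = None) -> "GenotypeTable":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeTable(
            sample_ids=[self.sample_ids[i] for i in si],
            snp_ids=[self.snp_ids[j] for j in vi],
            ref_allele=self.ref_allele[vi],
            alt_allele=self.alt_allele[vi],
            status=self.status[np.ix_(si, vi)],
            dosage=self.dosage[np.ix_(si, vi)],
        )

    def missing_fraction_per_sample(self) -> np.ndarray:
        return (self.status == MISSING).mean(axis=1)

    def missing_fraction_per_snp(self) -> np.ndarray:
        return (self.status == MISSING).mean(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for i, s in enumerate(self.sample_ids):
            for j, v in enumerate(self.snp_ids):
                d = int(self.dosage[i, j])
                gt = "./." if d < 0 else ["0/0", "0/1", "1/1"][d]
                rows.append((s, v, self.ref_allele[j], self.alt_allele[j], gt))
        pd.DataFrame(rows, columns=["sample_id", "snp_id", "ref", "alt", "genotype"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class PhenotypeTable:
    """Continuous phenotypes (IDPs): sample x IDP real values, NaN = missing."""

    values: pd.DataFrame  # index sample_id, columns idp_id

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate idp_id in phenotype table")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def idp_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, index_col="sample_id"))


@dataclass
class CovariateTable:
    """Named real/binary covariate columns (age, sex, smoking, height, BMI, PCs)."""

    values: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CovariateTable":
        return cls(pd.read_csv(path, index_col="sample_id"))


@dataclass
class DiseaseTable:
    """Binary disease indicators: sample x disease in {0, 1}."""

    indicator: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.indicator.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise FormatError("disease indicators must be strictly binary")
        self.indicator = self.indicator.astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicator.index)

    @property
    def disease_ids(self) -> list[str]:
        return list(self.indicator.columns)

    def to_csv(self, path: str | Path) -> None:
        self.indicator.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DiseaseTable":
        return cls(pd.read_csv(path, index_col="sample_id"))


@dataclass
class SnpCatalog:
    """SNP-disease association catalog rows: (snp_id, disease_id, assoc_p)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"snp_id", "disease_id", "assoc_p"}
        if not need.issubset(self.rows.columns):
            raise FormatError(f"catalog needs columns {sorted(need)}")
        if self.rows.duplicated(["snp_id", "disease_id"]).any():
            raise FormatError("duplicate (snp_id, disease_id) in catalog")
        p = self.rows["assoc_p"].to_numpy(float)
        if not ((p > 0) & (p <= 1)).all():
            raise FormatError("assoc_p must lie in (0, 1]")

    @property
    def snp_ids(self) -> list[str]:
        return sorted(self.rows["snp_id"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpCatalog":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class RiskScoreTable:
    """External per-sample risk scores, one column per disease."""

    scores: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RiskScoreTable":
        return cls(pd.read_csv(path, index_col="sample_id"))


def require_same_samples(*tables) -> list[str]:
    """Check that sample ids agree across modalities; never silently joins.

    Returns the sample order of the first table; raises AlignmentError listing
    the offending ids otherwise.
    """
    ref = list(tables[0].sample_ids)
    ref_set = set(ref)
    for t in tables[1:]:
        s = set(t.sample_ids)
        if s != ref_set:
            missing = sorted(ref_set - s)[:5]
            extra = sorted(s - ref_set)[:5]
            raise AlignmentError(
                f"sample ids differ across tables (missing e.g. {missing}, "
                f"unexpected e.g. {extra}); align inputs explicitly")
    return ref


# ---------------------------------------------------------------------------
# genotype readers

_GT_RE = re.compile(r"^(\.|\d+)([/|])(\.|\d+)$")


def _parse_gt(gt: str, line_no: int) -> tuple[int, int]:
    m = _GT_RE.match(gt.strip())
    if not m:
        raise FormatError(f"malformed genotype {gt!r} at line {line_no}")
    a1 = -1 if m.group(1) == "." else int(m.group(1))
    a2 = -1 if m.group(3) == "." else int(m.group(3))
    if a1 > 1 or a2 > 1:
        raise FormatError(f"only biallelic 0/1 alleles supported, got {gt!r} at line {line_no}")
    return a1, a2


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeTable:
    """Read genotypes from VCF or the TSV dialect into a GenotypeTable."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz", ".bcf") else "tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    status_cols: list[np.ndarray] = []
    dosage_cols: list[np.ndarray] = []
    seen: set[str] = set()
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        if vid in seen:
            raise FormatError(f"duplicate snp_id {vid!r} in {path}")
        seen.add(vid)
        if len(var.ALT) != 1:
            raise FormatError(f"variant {vid!r} is not biallelic")
        ref, alt = var.REF, var.ALT[0]
        st = np.empty(len(sample_ids), dtype=np.int8)
        ds = np.empty(len(sample_ids), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a1, a2 = int(g[0]), int(g[1])
            st[i], ds[i] = status_from_genotype(ref, alt, a1, a2)
        snp_ids.append(vid)
        refs.append(ref)
        alts.append(alt)
        status_cols.append(st)
        dosage_cols.append(ds)
    if not snp_ids:
        raise FormatError(f"no variants in {path}")
    return GenotypeTable(
        sample_ids=sample_ids, snp_ids=snp_ids,
        ref_allele=np.array(refs, dtype=object), alt_allele=np.array(alts, dtype=object),
        status=np.column_stack(status_cols), dosage=np.column_stack(dosage_cols))


def _read_genotype_tsv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["sample_id", "snp_id", "ref", "alt", "genotype"]
    if list(df.columns) != need:
        raise FormatError(f"genotype TSV must have columns {need}, got {list(df.columns)}")
    if df.duplicated(["sample_id", "snp_id"]).any():
        dup = df[df.duplicated(["sample_id", "snp_id"])].iloc[0]
        raise FormatError(f"duplicate record for sample {dup.sample_id!r} snp {dup.snp_id!r}")
    alleles = df.drop_duplicates("snp_id")[["snp_id", "ref", "alt"]]
    if df.groupby("snp_id")[["ref", "alt"]].nunique().gt(1).any().any():
        raise FormatError("inconsistent ref/alt alleles for a snp_id")
    sample_ids = list(dict.fromkeys(df["sample_id"]))
    snp_ids = list(alleles["snp_id"])
    s_index = {s: i for i, s in enumerate(sample_ids)}
    v_index = {v: j for j, v in enumerate(snp_ids)}
    ref = alleles.set_index("snp_id")["ref"]
    alt = alleles.set_index("snp_id")["alt"]
    status = np.full((len(sample_ids), len(snp_ids)), MISSING, dtype=np.int8)
    dosage = np.full_like(status, MISSING_DOSAGE)
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        a1, a2 = _parse_gt(row.genotype, line_no)
        st, ds = status_from_genotype(row.ref, row.alt, a1, a2)
        status[s_index[row.sample_id], v_index[row.snp_id]] = st
        dosage[s_index[row.sample_id], v_index[row.snp_id]] = ds
    return GenotypeTable(sample_ids=sample_ids, snp_ids=snp_ids,
                         ref_allele=np.array(ref, dtype=object),
                         alt_allele=np.array(alt, dtype=object),
                         status=status, dosage=dosage)


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no larger than the observed one
    (the standard SNP exact test).
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het = h | n, n_rare) up to a shared constant
    logp = (hets * np.log(2.0)
            - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def hwe_chi2_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """1-df chi-square Hardy-Weinberg test from genotype counts."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom1 + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    if (exp == 0).any():
        return 1.0  # monomorphic; leave to the MAF filter
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2_dist.sf(stat, df=1))


def snp_hwe_p(dosages: np.ndarray, exact_max_n: int = 1000) -> float:
    """HWE p for one SNP's dosage vector (missing entries ignored)."""
    d = dosages[dosages >= 0]
    n_hom1 = int((d == 0).sum())
    n_het = int((d == 1).sum())
    n_hom2 = int((d == 2).sum())
    if len(d) < exact_max_n:
        return hwe_exact_p(n_het, n_hom1, n_hom2)
    return hwe_chi2_p(n_het, n_hom1, n_hom2)


def snp_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from dosages, ignoring missing entries."""
    d = dosages[dosages >= 0]
    if len(d) == 0:
        return 0.0
    af = d.mean() / 2.0
    return float(min(af, 1.0 - af))


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    removals: pd.DataFrame  # columns: kind, id, reason, value
    notes: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for note in self.notes:
                fh.write(f"# {note}\n")
            self.removals.to_csv(fh, sep="\t", index=False)


class EmptyAfterQCError(ValueError):
    pass


def qc_filter(gt: GenotypeTable, cfg) -> tuple[GenotypeTable, QCReport]:
    """Apply sample-level then SNP-level genotype QC.

    Order is fixed by contract: sample missingness first (it changes the
    denominators of every SNP statistic), then SNP missingness, MAF and HWE
    computed on the retained samples.  Because dropping SNPs can raise a
    remaining sample's missing fraction (and vice versa), the sample->SNP
    round repeats until no further removal occurs, so the filter is
    idempotent: its output always satisfies both criteria jointly.
    """
    if gt.n_samples == 0 or gt.n_snps == 0:
        raise EmptyAfterQCError("empty genotype table")
    removals: list[tuple[str, str, str, float]] = []
    gt2 = gt
    changed = True
    while changed:
        changed = False

        miss_s = gt2.missing_fraction_per_sample()
        keep_s = miss_s <= cfg.sample_missing_max
        for i in np.flatnonzero(~keep_s):
            removals.append(("sample", gt2.sample_ids[i], "missingness", float(miss_s[i])))
        if not keep_s.any():
            raise EmptyAfterQCError("all samples removed: empty after QC")
        if not keep_s.all():
            gt2 = gt2.subset(sample_idx=np.flatnonzero(keep_s))
            changed = True

        keep_v = np.ones(gt2.n_snps, dtype=bool)
        miss_v = gt2.missing_fraction_per_snp()
        for j in range(gt2.n_snps):
            dos = gt2.dosage[:, j]
            if miss_v[j] > cfg.snp_missing_max:
                removals.append(("snp", gt2.snp_ids[j], "missingness", float(miss_v[j])))
                keep_v[j] = False
                continue
            maf = snp_maf(dos)
            if maf < cfg.maf_min:
                removals.append(("snp", gt2.snp_ids[j], "maf", maf))
                keep_v[j] = False
                continue
            hwe = snp_hwe_p(dos)
            if hwe < cfg.hwe_p_min:
                removals.append(("snp", gt2.snp_ids[j], "hwe", hwe))
                keep_v[j] = False
        if not keep_v.any():
            raise EmptyAfterQCError("all SNPs removed: empty after QC")
        if not keep_v.all():
            gt2 = gt2.subset(snp_idx=np.flatnonzero(keep_v))
            changed = True

    report = QCReport(
        removals=pd.DataFrame(removals, columns=["kind", "id", "reason", "value"]),
        notes=[
            "heterozygosity-rate variance filter: not applied (no threshold defined)",
            "relatedness filter: not applied (no threshold defined)",
        ],
    )
    return gt2, report


# ---------------------------------------------------------------------------
# pair-score table round trip

PAIR_SCORE_COLUMNS = ["idp_id", "snp_id", "n_correct", "n_seen",
                      "chi2", "chi2_corrected", "p", "p_adj"]


def write_pair_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a finalized pair-score table as TSV, sorted by adjusted p."""
    missing = [c for c in PAIR_SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pair score table missing columns {missing}")
    out = table[PAIR_SCORE_COLUMNS].sort_values(
        ["p_adj", "p", "idp_id", "snp_id"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pair_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PAIR_SCORE_COLUMNS:
        raise FormatError(f"pair score TSV must have columns {PAIR_SCORE_COLUMNS}")
    return df
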