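"""Synthetic cohorts with the statistical structure the pair learner assumes.

The generative direction makes the disease-mediation assumption literally
true for planted pairs: SNP dosages are drawn binomial(2, MAF) i.i.d. across
samples; each disease indicator is a Bernoulli draw from a logistic function
of its cataloged SNPs' centred dosages (so catalog links are statistically
real); each IDP is a linear function of its planted SNPs' dosages plus
disease shifts, covariate terms and Gaussian noise.  Cross pairs that share a
mediating disease but have no planted dosage effect (beta = 0) act as decoys,
so spurious-pair behaviour is testable against an exact ground truth.

Two ready-made designs cover the package's experiments:

* :func:`planted_bijection_spec` — each planted (SNP, IDP) pair has its own
  mediating disease plus one beta=0 decoy SNP, so pair expansion yields a
  clean dictionary in which every SNP has exactly one true IDP partner.
* :func:`single_disease_spec` — one disease mediates every SNP and IDP, so
  pair expansion yields the full cross product: a small planted diagonal in a
  sea of decoys, the regime the pair-significance statistics are built for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io import (GenotypeTable, PhenotypeTable, CovariateTable, DiseaseTable,
                 SnpCatalog, RiskScoreTable, HOM_REF, HET, HOM_ALT, MISSING,
                 MISSING_DOSAGE)


@dataclass(frozen=True)
class CatalogLink:
    snp_id: str
    disease_id: str
    assoc_p: float


@dataclass(frozen=True)
class IdpLink:
    idp_id: str
    disease_id: str
    shift: float = 0.0  # additive effect of the disease indicator on the IDP


@dataclass(frozen=True)
class TruePair:
    snp_id: str
    idp_id: str
    beta: float  # effect per alt-allele dosage, in IDP units


class SimSpecError(ValueError):
    pass


@dataclass
class SimSpec:
    n_samples: int
    snp_ids: list[str]
    idp_ids: list[str]
    disease_ids: list[str]
    disease_prevalence: dict[str, float]
    catalog_links: list[CatalogLink]
    idp_links: list[IdpLink]
    true_pairs: list[TruePair]
    maf: dict[str, float]
    noise_sd: float = 1.0
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    link_weight_scale: float = 0.25  # logistic weight per -log10(assoc_p)
    n_pcs: int = 10
    seed: int = 7

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 2:
            raise SimSpecError("need at least 2 samples")
        for v, maf in self.maf.items():
            if not (0.05 < maf < 0.5):
                raise SimSpecError(f"maf for {v} must lie in (0.05, 0.5), got {maf}")
        if set(self.maf) != set(self.snp_ids):
            raise SimSpecError("maf must be given for exactly the declared SNPs")
        for d in self.disease_ids:
            prev = self.disease_prevalence.get(d)
            if prev is None or not (0 < prev < 1):
                raise SimSpecError(f"prevalence for {d} must lie in (0, 1), got {prev}")
        for l in self.catalog_links:
            if not (0 < l.assoc_p <= 1):
                raise SimSpecError(f"assoc_p out of (0, 1] for {l}")
            if l.snp_id not in self.maf or l.disease_id not in self.disease_ids:
                raise SimSpecError(f"catalog link references unknown ids: {l}")
        snp_dis: dict[str, set[str]] = {}
        for l in self.catalog_links:
            snp_dis.setdefault(l.snp_id, set()).add(l.disease_id)
        idp_dis: dict[str, set[str]] = {}
        for l in self.idp_links:
            if l.idp_id not in self.idp_ids or l.disease_id not in self.disease_ids:
                raise SimSpecError(f"idp link references unknown ids: {l}")
            idp_dis.setdefault(l.idp_id, set()).add(l.disease_id)
        for tp in self.true_pairs:
            shared = snp_dis.get(tp.snp_id, set()) & idp_dis.get(tp.idp_id, set())
            if not shared:
                raise SimSpecError(
                    f"true pair {tp.snp_id}-{tp.idp_id} shares no mediating disease")
        if not (0 <= self.missing_rate < 1):
            raise SimSpecError("missing_rate must lie in [0, 1)")

    def true_pair_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(tp.snp_id, tp.idp_id, tp.beta) for tp in self.true_pairs],
                            columns=["snp_id", "idp_id", "beta"])


Cohort = tuple[GenotypeTable, PhenotypeTable, CovariateTable, DiseaseTable, SnpCatalog]


def simulate_cohort(spec: SimSpec) -> Cohort:
    """Draw a full cohort (genotypes, IDPs, covariates, diseases, catalog)."""
    root = np.random.SeedSequence(spec.seed)
    rng_geno, rng_cov, rng_dis, rng_idp, rng_miss = (
        np.random.default_rng(s) for s in root.spawn(5))
    n = spec.n_samples
    snps, idps, diseases = spec.snp_ids, spec.idp_ids, spec.disease_ids
    sample_ids = [f"S{i:05d}" for i in range(n)]

    mafs = np.array([spec.maf[v] for v in snps])
    dosage = rng_geno.binomial(2, mafs, size=(n, len(snps))).astype(np.int8)
    status = np.where(dosage == 0, HOM_REF, np.where(dosage == 1, HET, HOM_ALT)).astype(np.int8)
    if spec.missing_rate > 0:
        mask = rng_miss.random((n, len(snps))) < spec.missing_rate
        status[mask] = MISSING
        dosage = dosage.copy()
        dosage[mask] = MISSING_DOSAGE
    gt = GenotypeTable(
        sample_ids=sample_ids, snp_ids=list(snps),
        ref_allele=np.array(["A"] * len(snps), dtype=object),
        alt_allele=np.array(["G"] * len(snps), dtype=object),
        status=status, dosage=dosage)

    age = rng_cov.normal(60.0, 7.0, n)
    sex = rng_cov.integers(0, 2, n)
    cov = pd.DataFrame({
        "age": age,
        "sex": sex,
        "smoking": rng_cov.integers(0, 2, n),
        "height": rng_cov.normal(164.0, 8.0, n) + 12.0 * sex,
        "bmi": rng_cov.normal(27.0, 4.0, n),
    }, index=pd.Index(sample_ids, name="sample_id"))
    for k in range(spec.n_pcs):
        cov[f"PC{k + 1}"] = rng_cov.normal(0.0, 1.0, n)

    dose_clean = np.where(dosage < 0, 0, dosage).astype(float)
    centred = dose_clean - 2 * mafs  # centred alt-dosage per SNP
    snp_index = {v: j for j, v in enumerate(snps)}
    indicator = pd.DataFrame(0, index=pd.Index(sample_ids, name="sample_id"),
                             columns=diseases, dtype=int)
    for d in diseases:
        prev = spec.disease_prevalence[d]
        links = [l for l in spec.catalog_links if l.disease_id == d]
        if links:
            eta = np.zeros(n)
            for l in links:
                w = spec.link_weight_scale * (-np.log10(l.assoc_p))
                eta += w * centred[:, snp_index[l.snp_id]]
            # intercept calibrated so the mean risk matches the target prevalence
            alpha = brentq(lambda a: expit(a + eta).mean() - prev, -40.0, 40.0)
            risk = expit(alpha + eta)
        else:
            risk = np.full(n, prev)
        indicator[d] = (rng_dis.random(n) < risk).astype(int)
    dis = DiseaseTable(indicator)

    values = rng_idp.normal(0.0, spec.noise_sd, size=(n, len(idps)))
    idp_index = {p: k for k, p in enumerate(idps)}
    for tp in spec.true_pairs:
        values[:, idp_index[tp.idp_id]] += tp.beta * dose_clean[:, snp_index[tp.snp_id]]
    for l in spec.idp_links:
        if l.shift:
            values[:, idp_index[l.idp_id]] += l.shift * indicator[l.disease_id].to_numpy()
    for idp_id, effects in spec.covariate_effects.items():
        col = idp_index[idp_id]
        if "age" in effects:
            values[:, col] += effects["age"] * (age - age.mean()) / age.std()
        if "sex" in effects:
            values[:, col] += effects["sex"] * sex
    pheno = PhenotypeTable(pd.DataFrame(
        values, index=pd.Index(sample_ids, name="sample_id"), columns=idps))

    catalog = SnpCatalog(pd.DataFrame(
        [(l.snp_id, l.disease_id, l.assoc_p) for l in spec.catalog_links],
        columns=["snp_id", "disease_id", "assoc_p"]))
    return gt, pheno, CovariateTable(cov), dis, catalog


def simulate_risk_scores(disease: DiseaseTable, gt: GenotypeTable,
                         weights: Mapping[str, Mapping[str, float]],
                         sigma: float = 0.0, seed: int = 0) -> RiskScoreTable:
    """Per-sample synthetic risk scores: weighted dosage sums plus noise.

    ``weights`` maps disease id -> {snp_id: weight}.  Missing genotype calls
    contribute zero.  Stands in for an externally provided polygenic score.
    """
    rng = np.random.default_rng(seed)
    snp_index = {v: j for j, v in enumerate(gt.snp_ids)}
    dose = np.where(gt.dosage < 0, 0, gt.dosage).astype(float)
    out = {}
    for d, ws in weights.items():
        score = np.zeros(gt.n_samples)
        for snp_id, w in ws.items():
            if snp_id not in snp_index:
                raise KeyError(f"unknown snp_id {snp_id!r} in weights for {d!r}")
            score += w * dose[:, snp_index[snp_id]]
        if sigma > 0:
            score = score + rng.normal(0.0, sigma, gt.n_samples)
        out[d] = score
    return RiskScoreTable(pd.DataFrame(
        out, index=pd.Index(gt.sample_ids, name="sample_id")))


# ---------------------------------------------------------------------------
# ready-made designs


def planted_bijection_spec(n_samples: int = 2000, n_idps: int = 10,
                           beta: float = 2.0, noise_sd: float = 0.1,
                           maf: float = 0.3, prevalence: float = 0.3,
                           decoy_snps: bool = True, seed: int = 7) -> SimSpec:
    """Cohort with one strongly planted SNP partner per IDP.

    Each planted pair (snp_k, idp_k) is mediated by its own disease, generated
    from snp_k's dosage; when ``decoy_snps`` is set, a second cataloged SNP
    with no IDP effect joins each disease, so the expanded pair dictionary
    contains one true and one decoy pair per IDP (20 SNPs, 10 IDPs total in
    the default configuration).
    """
    n_snps = 2 * n_idps if decoy_snps else n_idps
    snps = [f"rs{j:04d}" for j in range(n_snps)]
    idps = [f"idp_{k:03d}" for k in range(n_idps)]
    diseases = [f"disease_{k}" for k in range(n_idps)]
    catalog = [CatalogLink(snps[k], diseases[k], 1e-12) for k in range(n_idps)]
    if decoy_snps:
        catalog += [CatalogLink(snps[n_idps + k], diseases[k], 1e-6)
                    for k in range(n_idps)]
    return SimSpec(
        n_samples=n_samples, snp_ids=snps, idp_ids=idps, disease_ids=diseases,
        disease_prevalence={d: prevalence for d in diseases},
        catalog_links=catalog,
        idp_links=[IdpLink(idps[k], diseases[k], 0.0) for k in range(n_idps)],
        true_pairs=[TruePair(snps[k], idps[k], beta) for k in range(n_idps)],
        maf={v: maf for v in snps}, noise_sd=noise_sd, seed=seed)


def single_disease_spec(n_samples: int = 2000, n_snps: int = 6, n_idps: int = 6,
                        beta: float = 2.0, noise_sd: float = 0.1,
                        maf: float = 0.3, prevalence: float = 0.3,
                        seed: int = 7) -> SimSpec:
    """Cohort in which one disease mediates every SNP and IDP.

    Pair expansion yields the full n_snps x n_idps cross product; the planted
    diagonal (snp_k, idp_k) for k < n_idps carries the only real dosage
    effects, every off-diagonal pair is a beta = 0 decoy.
    """
    if n_snps < n_idps:
        raise SimSpecError("need at least one SNP per IDP")
    snps = [f"rs{j:04d}" for j in range(n_snps)]
    idps = [f"idp_{k:03d}" for k in range(n_idps)]
    disease = "disease_0"
    return SimSpec(
        n_samples=n_samples, snp_ids=snps, idp_ids=idps, disease_ids=[disease],
        disease_prevalence={disease: prevalence},
        catalog_links=[CatalogLink(v, disease, 10.0 ** -(12 - j % 4))
                       for j, v in enumerate(snps)],
        idp_links=[IdpLink(p, disease, 0.0) for p in idps],
        true_pairs=[TruePair(snps[k], idps[k], beta) for k in range(n_idps)],
        maf={v: maf for v in snps}, noise_sd=noise_sd, seed=seed)


def write_cohort(cohort: Cohort, out_dir: str | Path,
                 spec: SimSpec | None = None) -> None:
    """Write the five tables (and the ground truth, if given) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt, pheno, cov, dis, catalog = cohort
    gt.to_tsv(out / "genotypes.tsv")
    pheno.to_csv(out / "phenotypes.csv")
    cov.to_csv(out / "covariates.csv")
    dis.to_csv(out / "diseases.csv")
    catalog.to_tsv(out / "catalog.tsv")
    if spec is not None:
        spec.true_pair_frame().to_csv(out / "true_pairs.tsv", sep="\t", index=False)
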