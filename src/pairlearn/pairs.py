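"""Disease-mediated (IDP, SNP) pair supervision.

A supervision pair exists between an IDP and a SNP when both are linked to
the same disease: the SNP through the association catalog, the IDP through a
phenome-wide scan (logistic regression of each disease on each standardized
IDP with covariates, Bonferroni-corrected Wald tests).  Each surviving
(IDP, disease) x (SNP, disease) combination is expanded across samples into
one record per sample, the atom of contrastive training.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import (SnpCatalog, PhenotypeTable, DiseaseTable, CovariateTable,
                 require_same_samples)

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["sample_id", "idp_id", "snp_id", "disease_id"]


class PairRecord(NamedTuple):
    sample_id: str
    idp_id: str
    snp_id: str
    disease_id: str


def select_top_snps(catalog: SnpCatalog, percent: float) -> SnpCatalog:
    """Keep catalog rows of the strongest ceil(percent% x unique SNPs) SNPs.

    A SNP's strength is its minimum association p over diseases; ties at the
    cutoff break lexically by (assoc_p, snp_id).
    """
    if not (0 < percent <= 100):
        raise ValueError(f"percent must lie in (0, 100], got {percent}")
    rows = catalog.rows
    if rows.empty:
        raise ValueError("empty catalog")
    strength = rows.groupby("snp_id")["assoc_p"].min().reset_index()
    strength = strength.sort_values(["assoc_p", "snp_id"], kind="mergesort")
    n_keep = math.ceil(percent / 100.0 * len(strength))
    keep = set(strength["snp_id"].head(n_keep))
    return SnpCatalog(rows[rows["snp_id"].isin(keep)].reset_index(drop=True))


def map_idps_to_diseases(pheno: PhenotypeTable, dis: DiseaseTable,
                         cov: CovariateTable, alpha: float = 0.05) -> pd.DataFrame:
    """Phenome-wide scan: logistic disease ~ standardized IDP + covariates.

    Returns one row per tested (idp, disease) with the IDP coefficient's Wald
    p-value and a ``passed`` flag at the Bonferroni level
    alpha / (n_idps * n_diseases).  Degenerate or non-converged fits are
    recorded with p = 1 and flagged.
    """
    order = require_same_samples(pheno, dis, cov)
    P = pheno.values.loc[order]
    D = dis.indicator.loc[order]
    C = cov.values.loc[order].astype(float)
    # drop constant covariate columns; standardize the rest for conditioning
    C = C.loc[:, C.std() > 0]
    Cz = (C - C.mean()) / C.std()
    X_cov = sm.add_constant(Cz.to_numpy(), has_constant="add")

    n_tests = len(P.columns) * len(D.columns)
    threshold = alpha / n_tests
    rows = []
    for disease_id in D.columns:
        y = D[disease_id].to_numpy()
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(f"disease {disease_id!r} needs at least one case and one control")
        for idp_id in P.columns:
            x = P[idp_id].to_numpy(float)
            x = np.where(np.isnan(x), np.nanmean(x), x)
            sd = x.std()
            if sd == 0 or not np.isfinite(sd):
                log.warning("idp %s has zero variance; recorded as failed", idp_id)
                rows.append((idp_id, disease_id, 1.0, False, True))
                continue
            xz = (x - x.mean()) / sd
            X = np.column_stack([X_cov, xz])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
                p = float(fit.pvalues[-1])
                flagged = not fit.mle_retvals.get("converged", True)
                if not np.isfinite(p):
                    p, flagged = 1.0, True
            except Exception as exc:  # separation, singular matrix, ...
                log.warning("phewas fit failed for (%s, %s): %s", idp_id, disease_id, exc)
                p, flagged = 1.0, True
            if flagged:
                p = 1.0
                log.warning("phewas fit flagged for (%s, %s)", idp_id, disease_id)
            rows.append((idp_id, disease_id, p, p < threshold, flagged))
    return pd.DataFrame(rows, columns=["idp_id", "disease_id", "p", "passed", "flagged"])


class NoMediatedPairsError(ValueError):
    pass


def build_pairs(selected: SnpCatalog, idp_map: pd.DataFrame,
                sample_ids: Sequence[str]) -> pd.DataFrame:
    """Expand disease-mediated (IDP, SNP) combinations across samples.

    For every disease, all passing IDPs are crossed with all selected SNPs of
    that disease, then expanded to one record per sample.  Duplicate
    (sample, idp, snp) records arising from multiple mediators keep the
    mediator whose catalog association p is smallest.
    """
    passing = idp_map[idp_map["passed"]][["idp_id", "disease_id"]]
    cat = selected.rows
    combos = passing.merge(cat, on="disease_id")  # idp_id, disease_id, snp_id, assoc_p
    if combos.empty:
        raise NoMediatedPairsError("no disease has both a passing IDP and a selected SNP")
    combos = (combos.sort_values(["assoc_p", "disease_id"], kind="mergesort")
              .drop_duplicates(["idp_id", "snp_id"], keep="first"))
    combos = combos[["idp_id", "snp_id", "disease_id"]].reset_index(drop=True)
    samples = pd.DataFrame({"sample_id": list(sample_ids)})
    records = samples.merge(combos, how="cross")
    return records[PAIR_COLUMNS]


@dataclass
class PairSplit:
    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    fractions: tuple[float, float, float]
    seed: int
    mode: str

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def split_pairs(records: pd.DataFrame, fractions=(0.70, 0.20, 0.10),
                seed: int = 7, mode: str = "by_pair") -> PairSplit:
    """Split pair records 70/20/10 into train/val/test.

    ``by_pair`` shuffles records and cuts at the fractions (a sample's records
    may then cross splits); ``by_sample`` assigns whole samples to splits so
    no sample crosses splits.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(records) < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(seed)
    if mode == "by_pair":
        perm = rng.permutation(len(records))
        shuffled = records.iloc[perm].reset_index(drop=True)
        n_train = int(math.floor(fractions[0] * len(records)))
        n_val = int(math.floor(fractions[1] * len(records)))
        parts = (shuffled.iloc[:n_train],
                 shuffled.iloc[n_train:n_train + n_val],
                 shuffled.iloc[n_train + n_val:])
    elif mode == "by_sample":
        samples = np.array(sorted(records["sample_id"].unique()))
        rng.shuffle(samples)
        n_train = int(math.floor(fractions[0] * len(samples)))
        n_val = int(math.floor(fractions[1] * len(samples)))
        groups = (set(samples[:n_train]), set(samples[n_train:n_train + n_val]),
                  set(samples[n_train + n_val:]))
        parts = tuple(records[records["sample_id"].isin(g)].reset_index(drop=True)
                      for g in groups)
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    train, val, test = (p.reset_index(drop=True) for p in parts)
    return PairSplit(train=train, val=val, test=test,
                     fractions=tuple(fractions), seed=seed, mode=mode)
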