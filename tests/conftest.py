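import numpy as np
import pytest

import pairlearn as pl


@pytest.fixture(scope="session")
def bijection_cohort():
    """Small planted-bijection cohort: 5 IDPs, 10 SNPs (5 planted, 5 decoy)."""
    spec = pl.planted_bijection_spec(n_samples=400, n_idps=5, beta=2.0,
                                     noise_sd=0.1, seed=11)
    gt, pheno, cov, dis, catalog = pl.simulate_cohort(spec)
    return {"spec": spec, "gt": gt, "pheno": pheno, "cov": cov,
            "dis": dis, "catalog": catalog}


@pytest.fixture(scope="session")
def trained_bijection(bijection_cohort):
    """One trained model on the bijection cohort, shared across tests."""
    c = bijection_cohort
    cfg = pl.RunConfig(batch_size=32, max_epochs=8, warmup_steps=30,
                       n_bins=8, patience=8, seed=11)
    gt2, _ = pl.qc_filter(c["gt"], cfg)
    sel = pl.select_top_snps(c["catalog"], 100)
    idp_map = pl.map_idps_to_diseases(c["pheno"], c["dis"], c["cov"])
    records = pl.build_pairs(sel, idp_map, gt2.sample_ids)
    split = pl.split_pairs(records, seed=cfg.seed)
    result = pl.train(split, gt2, c["pheno"], cfg)
    log = pl.evaluate(result.model, result.tokenizer, split.test, gt2,
                      c["pheno"], cfg.batch_size)
    return {"cfg": cfg, "gt": gt2, "split": split, "result": result, "log": log,
            "pheno": c["pheno"], "cov": c["cov"], "dis": c["dis"],
            "spec": c["spec"]}
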