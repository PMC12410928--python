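import numpy as np
import pandas as pd
import pytest

import pairlearn as pl
from pairlearn.io import SnpCatalog, PhenotypeTable, DiseaseTable, CovariateTable
from pairlearn.pairs import (select_top_snps, map_idps_to_diseases, build_pairs,
                             split_pairs, NoMediatedPairsError)


def catalog_of(rows):
    return SnpCatalog(pd.DataFrame(rows, columns=["snp_id", "disease_id", "assoc_p"]))


class TestSelectTopSnps:
    def test_percent_one_of_200(self):
        rows = [(f"rs{j:03d}", "d", (j + 1) / 1000) for j in range(200)]
        out = select_top_snps(catalog_of(rows), 1)
        assert sorted(out.rows["snp_id"]) == ["rs000", "rs001"]  # ceil(2.0) = 2

    def test_percent_100_identity(self):
        cat = catalog_of([("rs1", "d", 0.5), ("rs2", "d", 0.1)])
        out = select_top_snps(cat, 100)
        assert sorted(out.rows["snp_id"]) == ["rs1", "rs2"]

    def test_tie_break_lexical(self):
        cat = catalog_of([("rsB", "d", 0.01), ("rsA", "d", 0.01), ("rsC", "d", 0.5)])
        out = select_top_snps(cat, 34)  # ceil(0.34*3) = 2... one slot after rs?
        # ceil(1.02) = 2 SNPs kept: both tied at 0.01 fit; shrink to one slot
        out1 = select_top_snps(cat, 33)  # ceil(0.99) = 1 SNP
        assert list(out1.rows["snp_id"].unique()) == ["rsA"]

    def test_strength_is_min_over_diseases(self):
        cat = catalog_of([("rs1", "d1", 0.9), ("rs1", "d2", 1e-9),
                          ("rs2", "d1", 0.01)])
        out = select_top_snps(cat, 50)  # keeps 1 of 2 unique SNPs
        assert set(out.rows["snp_id"]) == {"rs1"}
        # all catalog rows of a kept SNP survive, including the weak one
        assert len(out.rows) == 2

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            select_top_snps(catalog_of([("rs1", "d", 0.5)]).__class__(
                pd.DataFrame(columns=["snp_id", "disease_id", "assoc_p"])), 10)


@pytest.fixture(scope="module")
def cohort():
    spec = pl.planted_bijection_spec(n_samples=1200, n_idps=3, seed=3)
    return pl.simulate_cohort(spec)


class TestPhewas:
    def test_planted_links_pass(self, cohort):
        gt, pheno, cov, dis, cat = cohort
        m = map_idps_to_diseases(pheno, dis, cov)
        planted = m[(m.idp_id == "idp_000") & (m.disease_id == "disease_0")]
        assert bool(planted["passed"].iloc[0])

    def test_unlinked_pairs_do_not_pass(self, cohort):
        gt, pheno, cov, dis, cat = cohort
        m = map_idps_to_diseases(pheno, dis, cov)
        cross = m[(m.idp_id == "idp_000") & (m.disease_id == "disease_2")]
        assert not bool(cross["passed"].iloc[0])

    def test_zero_variance_idp_flagged(self, cohort):
        gt, pheno, cov, dis, cat = cohort
        pv = pheno.values.copy()
        pv["flat"] = 1.0
        m = map_idps_to_diseases(PhenotypeTable(pv), dis, cov)
        rows = m[m.idp_id == "flat"]
        assert (~rows["passed"]).all() and rows["flagged"].all()
        assert (rows["p"] == 1.0).all()

    def test_single_class_disease_rejected(self, cohort):
        gt, pheno, cov, dis, cat = cohort
        ind = dis.indicator.copy()
        ind["disease_0"] = 0
        with pytest.raises(ValueError, match="case"):
            map_idps_to_diseases(pheno, DiseaseTable(ind), cov)

    def test_type_i_control_under_bonferroni(self):
        """Null IDPs tested against independent diseases rarely pass."""
        false_pass = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            n = 300
            ids = [f"S{i}" for i in range(n)]
            pheno = PhenotypeTable(pd.DataFrame(
                rng.normal(size=(n, 4)), index=ids,
                columns=[f"i{k}" for k in range(4)]))
            dis = DiseaseTable(pd.DataFrame(
                {"d0": rng.binomial(1, 0.3, n), "d1": rng.binomial(1, 0.3, n)},
                index=ids))
            cov = CovariateTable(pd.DataFrame(
                {"age": rng.normal(60, 7, n), "sex": rng.integers(0, 2, n)}, index=ids))
            m = map_idps_to_diseases(pheno, dis, cov)
            false_pass += int(m["passed"].sum())
        # 15 runs x 8 Bonferroni-guarded tests: expect ~0.75 false passes at
        # family level 0.05; 3+ would signal broken calibration
        assert false_pass <= 2


class TestBuildPairs:
    def test_cross_product_count(self):
        sel = catalog_of([("s1", "d", 1e-8), ("s2", "d", 1e-6)])
        idpmap = pd.DataFrame({"idp_id": ["i1"], "disease_id": ["d"],
                               "p": [1e-9], "passed": [True], "flagged": [False]})
        recs = build_pairs(sel, idpmap, [f"p{i}" for i in range(10)])
        assert len(recs) == 20  # 2 SNPs x 1 IDP x 10 samples

    def test_dedup_keeps_strongest_mediator(self):
        sel = catalog_of([("s1", "d1", 1e-4), ("s1", "d2", 1e-9)])
        idpmap = pd.DataFrame({"idp_id": ["i1", "i1"], "disease_id": ["d1", "d2"],
                               "p": [1e-9, 1e-9], "passed": [True, True],
                               "flagged": [False, False]})
        recs = build_pairs(sel, idpmap, ["p1"])
        assert len(recs) == 1
        assert recs["disease_id"].iloc[0] == "d2"

    def test_no_cross_disease_records(self):
        sel = catalog_of([("s1", "d1", 1e-8), ("s2", "d2", 1e-8)])
        idpmap = pd.DataFrame({"idp_id": ["i1", "i2"], "disease_id": ["d1", "d2"],
                               "p": [1e-9, 1e-9], "passed": [True, True],
                               "flagged": [False, False]})
        recs = build_pairs(sel, idpmap, ["p1"])
        combos = set(map(tuple, recs[["idp_id", "snp_id"]].to_numpy()))
        assert combos == {("i1", "s1"), ("i2", "s2")}

    def test_empty_result_raises(self):
        sel = catalog_of([("s1", "d1", 1e-8)])
        idpmap = pd.DataFrame({"idp_id": ["i1"], "disease_id": ["d2"],
                               "p": [1e-9], "passed": [True], "flagged": [False]})
        with pytest.raises(NoMediatedPairsError):
            build_pairs(sel, idpmap, ["p1"])

    def test_count_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        diseases = ["d0", "d1", "d2"]
        snps = [f"s{j}" for j in range(6)]
        idps = [f"i{k}" for k in range(4)]
        cat_rows = [(s, d, float(rng.uniform(1e-12, 1e-2)))
                    for s in snps for d in diseases if rng.random() < 0.5]
        idp_rows = [(i, d, 1e-9, bool(rng.random() < 0.6), False)
                    for i in idps for d in diseases]
        samples = [f"p{i}" for i in range(5)]
        sel = catalog_of(cat_rows)
        idpmap = pd.DataFrame(idp_rows, columns=["idp_id", "disease_id", "p",
                                                 "passed", "flagged"])
        recs = build_pairs(sel, idpmap, samples)
        # brute force: unique (idp, snp) combos sharing >= 1 mediating disease
        expected = set()
        for i, d_i, _, passed, _ in idp_rows:
            if not passed:
                continue
            for s, d_s, _ in cat_rows:
                if d_s == d_i:
                    expected.add((i, s))
        assert len(recs) == len(expected) * len(samples)
        assert set(map(tuple, recs[["idp_id", "snp_id"]].drop_duplicates()
                       .to_numpy())) == expected

    def test_referential_integrity(self):
        sel = catalog_of([("s1", "d", 1e-8), ("s2", "d", 1e-6)])
        idpmap = pd.DataFrame({"idp_id": ["i1"], "disease_id": ["d"],
                               "p": [1e-9], "passed": [True], "flagged": [False]})
        recs = build_pairs(sel, idpmap, ["p1", "p2"])
        valid_snp_d = set(map(tuple, sel.rows[["snp_id", "disease_id"]].to_numpy()))
        valid_idp_d = set(map(tuple,
                              idpmap[idpmap.passed][["idp_id", "disease_id"]].to_numpy()))
        for r in recs.itertuples(index=False):
            assert (r.snp_id, r.disease_id) in valid_snp_d
            assert (r.idp_id, r.disease_id) in valid_idp_d


class TestSplitPairs:
    def _records(self, n, n_samples=5):
        return pd.DataFrame({
            "sample_id": [f"p{i % n_samples}" for i in range(n)],
            "idp_id": ["i1"] * n, "snp_id": ["s1"] * n, "disease_id": ["d"] * n})

    def test_sizes_70_20_10(self):
        sp = split_pairs(self._records(10), seed=1)
        assert (len(sp.train), len(sp.val), len(sp.test)) == (7, 2, 1)

    def test_partition_is_exact(self):
        recs = self._records(97)
        sp = split_pairs(recs, seed=2)
        assert len(sp.train) + len(sp.val) + len(sp.test) == 97

    def test_same_seed_identical(self):
        a = split_pairs(self._records(50), seed=3)
        b = split_pairs(self._records(50), seed=3)
        pd.testing.assert_frame_equal(a.train, b.train)
        pd.testing.assert_frame_equal(a.test, b.test)

    def test_by_sample_disjoint(self):
        sp = split_pairs(self._records(200, n_samples=40), seed=4, mode="by_sample")
        s = [set(part["sample_id"]) for part in sp]
        assert not (s[0] & s[1]) and not (s[0] & s[2]) and not (s[1] & s[2])

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_pairs(self._records(2), seed=1)
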