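import numpy as np
import pandas as pd
import pytest
from scipy import stats

from inbredqtl import MarkerMap, ParameterError, compute_kinship, loco_set, make_map
from inbredqtl.errors import ConfigurationError
from inbredqtl.phenotypes import phenotype_frame, place_genes, simulate_genes, truth_frame
from inbredqtl.scan import (
    default_subpop_groups,
    improbable_recomb_filter,
    ols_test,
    run_scan,
    snp_qc,
    stouffer_combine,
    subpop_meta,
)


@pytest.fixture(scope="module")
def study(complete_panel, small_map):
    genes = place_genes(small_map, 12, seed=41, require_cis=True, panel=complete_panel)
    sims = simulate_genes(complete_panel, genes, "one_cis", np.full(12, 0.6), seed=42)
    return genes, phenotype_frame(sims, complete_panel.strain_ids), truth_frame(sims)


class TestSnpQc:
    def test_maf_arithmetic_at_both_thresholds(self, mixed_panel):
        # a singleton minor allele in 43 strains has MAF ~ 0.023: removed
        # at maf_min=0.10, retained at maf_min=0.001
        g = mixed_panel.genotypes.copy()
        g[:, 0] = 0.0
        g[0, 0] = 1.0
        panel = type(mixed_panel)(
            strain_ids=mixed_panel.strain_ids,
            subpopulation=mixed_panel.subpopulation,
            genotypes=g,
            map=mixed_panel.map,
            _skip_validation=True,
        )
        snp0 = panel.map.snp_id[0]
        _, strict = snp_qc(panel, maf_min=0.10, miss_max=1.0)
        assert snp0 not in strict.map.snp_id
        _, loose = snp_qc(panel, maf_min=0.001, miss_max=1.0)
        assert snp0 in loose.map.snp_id

    def test_missingness_threshold(self, complete_panel):
        g = complete_panel.genotypes.copy()
        g[:3, 1] = np.nan  # 3/43 ~ 0.070 >= 0.05 -> removed
        panel = type(complete_panel)(
            strain_ids=complete_panel.strain_ids,
            subpopulation=complete_panel.subpopulation,
            genotypes=g,
            map=complete_panel.map,
            _skip_validation=True,
        )
        report, filtered = snp_qc(panel, maf_min=0.0, miss_max=0.05)
        assert panel.map.snp_id[1] not in filtered.map.snp_id
        assert report.snps_removed_missing >= 1

    def test_monomorphic_removed(self, complete_panel):
        report, filtered = snp_qc(complete_panel, maf_min=0.10, miss_max=0.05)
        assert (filtered.minor_allele_frequency() > 0.10).all()
        assert report.snps_retained == filtered.n_snps
        assert (
            report.snps_retained + report.snps_removed_maf + report.snps_removed_missing
            == report.snps_input
        )


class TestRecombFilter:
    def _map(self, cms):
        n = len(cms)
        return MarkerMap(
            snp_id=np.array([f"s{i}" for i in range(n)]),
            chromosome=np.ones(n, dtype=int),
            pos_bp=np.arange(1, n + 1) * 10,
            pos_cM=np.asarray(cms, dtype=float),
        )

    def test_interior_removed_only_if_both_gaps_large(self):
        removed = improbable_recomb_filter(self._map([0, 25, 47, 52]))
        # s1: gaps (25, 22) both >= 20 -> removed; s2: gaps (22, 5) -> kept
        assert "s1" in removed and "s2" not in removed

    def test_terminal_single_gap_rule(self):
        removed = improbable_recomb_filter(self._map([0, 21, 22]))
        assert "s0" in removed  # terminal, single gap 21 >= 20
        assert "s2" not in removed  # terminal, gap 1

    def test_union_over_ri_populations(self):
        m1 = self._map([0, 25, 50])  # flags s1 (and terminals)
        m2 = self._map([0, 1, 2])  # flags nothing
        assert improbable_recomb_filter({"ri1": m2}) == []
        union = improbable_recomb_filter({"ri1": m1, "ri2": m2})
        assert "s1" in union


class TestOls:
    def test_perfect_fit_floors_p(self, rng):
        x = rng.integers(0, 2, 20).astype(float)
        while x.std() == 0:
            x = rng.integers(0, 2, 20).astype(float)
        t = ols_test(2.0 * x + 1.0, x)
        assert t.p_value <= 1e-300 and t.beta_hat == pytest.approx(2.0)

    def test_orthogonal_snp_p_near_one(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        t = ols_test(y, x)
        assert t.beta_hat == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_null_pvalues_uniform(self, rng):
        ps = []
        for _ in range(2000):
            y = rng.normal(size=30)
            x = rng.integers(0, 2, 30).astype(float)
            while x.std() == 0:
                x = rng.integers(0, 2, 30).astype(float)
            ps.append(ols_test(y, x).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_monomorphic_rejected(self):
        with pytest.raises(ParameterError):
            ols_test(np.arange(5.0), np.ones(5))


class TestRunScan:
    def test_identity_kinship_lmm_matches_ols(self, complete_panel, study):
        genes, phenos, _ = study
        from inbredqtl.kinship import KinshipMatrix

        eye = KinshipMatrix(
            strain_ids=list(complete_panel.strain_ids),
            values=np.eye(complete_panel.n_strains),
        )
        lmm_res, _ = run_scan(
            complete_panel, phenos, genes[:4], "lmm", kinship=eye, cis_only=True
        )
        ols_res, _ = run_scan(complete_panel, phenos, genes[:4], "ols", cis_only=True)
        merged = lmm_res.merge(ols_res, on=["gene_id", "snp_id"], suffixes=("_l", "_o"))
        assert len(merged) == len(lmm_res)
        np.testing.assert_allclose(merged["p_value_l"], merged["p_value_o"], atol=1e-6)

    def test_deterministic_output(self, complete_panel, mixed_kinship, study):
        genes, phenos, _ = study
        k = compute_kinship(complete_panel)
        a, _ = run_scan(complete_panel, phenos, genes[:3], "lmm", kinship=k, cis_only=True)
        b, _ = run_scan(complete_panel, phenos, genes[:3], "lmm", kinship=k, cis_only=True)
        pd.testing.assert_frame_equal(a, b)

    def test_loco_requires_all_chromosome_kinships(self, complete_panel, study):
        genes, phenos, _ = study
        loco = loco_set(complete_panel)
        loco.pop(list(loco)[0])
        with pytest.raises(ConfigurationError):
            run_scan(
                complete_panel, phenos, genes, "lmm_loco",
                loco_kinships=loco, cis_only=True,
            )

    def test_lmm_requires_kinship(self, complete_panel, study):
        genes, phenos, _ = study
        with pytest.raises(ConfigurationError):
            run_scan(complete_panel, phenos, genes, "lmm", cis_only=True)

    def test_rows_sorted_and_flagged(self, complete_panel, study):
        genes, phenos, _ = study
        res, _ = run_scan(complete_panel, phenos, genes[:3], "ols", cis_only=False)
        for _, grp in res.groupby("gene_id"):
            key = list(zip(grp["chromosome"], grp["pos_bp"]))
            assert key == sorted(key)
        assert res["is_cis"].any() and (~res["is_cis"]).any()
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()


class TestStouffer:
    def test_two_groups_worked_example(self):
        # p = 0.05 in both groups, same direction: z = 1.95996 each,
        # z_meta = 2.7718, p_meta = 0.00556
        z, p = stouffer_combine([0.05, 0.05], [1.0, 2.0])
        assert z == pytest.approx(2.0 * 1.959964 / np.sqrt(2.0), abs=1e-4)
        assert p == pytest.approx(0.00556, abs=5e-5)

    def test_single_group_identity(self):
        _, p = stouffer_combine([0.0123], [1.0])
        assert p == pytest.approx(0.0123, abs=1e-9)

    def test_opposite_directions_cancel(self):
        z, p = stouffer_combine([0.01, 0.01], [1.0, -1.0])
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestSubpopMeta:
    def test_meta_snp_set_within_each_group_qc(self, mixed_panel, small_map):
        genes = place_genes(small_map, 4, seed=51, require_cis=True, panel=mixed_panel)
        sims = simulate_genes(mixed_panel, genes, "one_cis", np.full(4, 0.5), seed=52)
        phenos = phenotype_frame(sims, mixed_panel.strain_ids)
        res, report = subpop_meta(mixed_panel, phenos, genes, cis_only=True)
        meta_ids = set(report.disposition.query("status == 'retained'")["snp_id"])
        for name, idx in default_subpop_groups(mixed_panel).items():
            grp_report, _ = snp_qc(mixed_panel.subset_strains(idx))
            grp_ids = set(grp_report.disposition.query("status == 'retained'")["snp_id"])
            assert meta_ids <= grp_ids

    def test_groups_need_minimum_size(self, mixed_panel, study):
        genes, phenos, _ = study
        groups = {"RI": np.arange(30), "CLASSIC": np.arange(30, 33)}
        with pytest.raises(ConfigurationError):
            subpop_meta(mixed_panel, phenos, genes, groups=groups)

    def test_meta_pvalues_valid(self, complete_panel, study):
        genes, phenos, _ = study
        res, _ = subpop_meta(complete_panel, phenos, genes[:4], cis_only=True)
        assert len(res) > 0
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()
        assert (res["method"] == "subpop_meta").all()
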