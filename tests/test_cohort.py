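"""Synthetic cohort generator: pedigrees, gene drop, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from pathstep import (CohortConfig, compute_kinship, drop_genotypes,
                      simulate_catalog, simulate_null_trait,
                      simulate_pedigrees, simulate_phenotypes)
from pathstep.cohort import (ConfigError, VariantCatalog,
                             expected_family_size, mask_genotypes)


class TestPedigreeSimulation:
    def test_fixed_template_count_closed_form(self):
        cfg = CohortConfig(seed=1, n_families=1, n_generations=3,
                           sibship_kind="fixed", sibship_size=2)
        ped = simulate_pedigrees(cfg)
        # founder couple (2) + 2 children + 2 spouses + 4 grandchildren
        assert expected_family_size(cfg) == 10
        assert ped.n == 10

    def test_same_seed_identical(self):
        cfg = CohortConfig(seed=3, n_families=4, sibship_kind="poisson")
        a = simulate_pedigrees(cfg)
        b = simulate_pedigrees(cfg)
        assert a.ids == b.ids
        assert [m.father for m in a.members] == \
            [m.father for m in b.members]

    def test_families_distinct_and_isolated(self):
        cfg = CohortConfig(seed=2, n_families=50, n_generations=2,
                           sibship_size=1)
        ped = simulate_pedigrees(cfg)
        assert len(ped.families) == 50
        for m in ped.members:
            if m.father is not None:
                assert ped[m.father].fid == m.fid

    def test_degenerate_template_rejected(self):
        with pytest.raises(ConfigError, match="generation"):
            simulate_pedigrees(CohortConfig(n_generations=0))


class TestCatalog:
    def test_catalog_invariants(self):
        cat = simulate_catalog(CohortConfig(seed=4, n_genes=20))
        df = cat.frame
        assert df["variant_id"].is_unique
        assert df["founder_maf"].between(0, 0.5, inclusive="right").all()
        for _, sub in df.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
        # causal fraction honoured
        n_causal = len(cat.causal_genes)
        assert n_causal == round(0.2 * 20)

    def test_rejects_nonincreasing_positions(self):
        df = simulate_catalog(CohortConfig(seed=4, n_genes=4)).frame.copy()
        df.loc[1, "pos"] = df.loc[0, "pos"]
        with pytest.raises(ValueError, match="increasing"):
            VariantCatalog(df)

    def test_null_copy_has_no_effects(self):
        cat = simulate_catalog(CohortConfig(seed=4, n_genes=10))
        assert cat.null_copy().causal_genes == []

    def test_tsv_roundtrip(self, tmp_path):
        cat = simulate_catalog(CohortConfig(seed=4, n_genes=5))
        cat.write_tsv(tmp_path / "cat.tsv", seed=4)
        back = VariantCatalog.read_tsv(tmp_path / "cat.tsv")
        pd.testing.assert_frame_equal(back.frame, cat.frame)


class TestGeneDrop:
    def test_child_of_homozygous_parents(self):
        from pathstep import Pedigree
        ped = Pedigree.build([("F", "X", None, None), ("M", "X", None, None),
                              ("C", "X", "F", "M")])
        cat = VariantCatalog(pd.DataFrame({
            "variant_id": ["v1"], "chrom": ["1"], "pos": [100],
            "gene_id": ["g"], "founder_maf": [0.01], "effect_beta": [0.0]}))
        for seed in range(40):
            gm = drop_genotypes(ped, cat, seed=seed)
            cf, cm, cc = gm.counts[:, 0]
            lo = (cf == 2) + (cm == 2)
            hi = (cf > 0) + (cm > 0)
            assert lo <= cc <= hi

    def test_mendelian_consistency_exhaustive(self, small_cohort):
        gm, ped = small_cohort["genotypes"], small_cohort["ped"]
        idx = {iid: k for k, iid in enumerate(gm.ids)}
        for m in ped.members:
            if m.is_founder:
                continue
            c = gm.counts[idx[m.iid]]
            cf = gm.counts[idx[m.father]]
            cm = gm.counts[idx[m.mother]]
            lo = (cf == 2).astype(int) + (cm == 2).astype(int)
            hi = (cf > 0).astype(int) + (cm > 0).astype(int)
            assert np.all((c >= lo) & (c <= hi))

    def test_founder_frequency_matches_maf(self):
        # 5,000 founders: binomial CI around the catalog MAF
        cfg = CohortConfig(seed=6, n_families=2500, n_generations=1,
                           n_genes=3)
        ped = simulate_pedigrees(cfg)
        cat = simulate_catalog(cfg)
        gm = drop_genotypes(ped, cat, seed=9)
        freq = gm.counts.mean(axis=0) / 2.0
        n_all = 2 * ped.n
        se = np.sqrt(cat.mafs * (1 - cat.mafs) / n_all)
        assert np.all(np.abs(freq - cat.mafs) <= 4 * se)

    def test_deterministic_given_seed(self, small_cohort):
        c = small_cohort
        gm2 = drop_genotypes(c["ped"], c["catalog"], seed=c["config"].seed)
        np.testing.assert_array_equal(gm2.counts, c["genotypes"].counts)

    def test_masking(self, small_cohort):
        gm = mask_genotypes(small_cohort["genotypes"], 0.1, seed=1)
        frac = np.isnan(gm.counts).mean()
        assert 0.05 < frac < 0.15


class TestPhenotypes:
    def test_degenerate_generator_constant_trait(self, small_cohort):
        cfg = CohortConfig(
            seed=1, n_families=2, polygenic_variance=0.0,
            residual_variance=0.0, exam_noise_variance=0.0,
            trait_noise_variance=0.0, age_slope_sbp=0.0, age_slope_dbp=0.0,
            male_effect_sbp=0.0, male_effect_dbp=0.0, smoke_effect_sbp=0.0,
            smoke_effect_dbp=0.0)
        ped = simulate_pedigrees(cfg)
        df = simulate_null_trait(ped, cfg, 0)
        np.testing.assert_allclose(df["SBP"], cfg.sbp_intercept)
        np.testing.assert_allclose(df["DBP"], cfg.dbp_intercept)
        assert (df["med"] == 0).all()

    def test_replicates_share_covariates_not_noise(self, small_cohort):
        c = small_cohort
        a = simulate_phenotypes(c["ped"], c["genotypes"], c["catalog"],
                                c["config"], 0, kin=c["kin"])
        b = simulate_phenotypes(c["ped"], c["genotypes"], c["catalog"],
                                c["config"], 1, kin=c["kin"])
        np.testing.assert_array_equal(a["age"], b["age"])
        np.testing.assert_array_equal(a["smoke"], b["smoke"])
        assert not np.allclose(a["SBP"], b["SBP"])

    def test_replicate_seed_idempotent(self, small_cohort):
        c = small_cohort
        a = simulate_null_trait(c["ped"], c["config"], 3, kin=c["kin"])
        b = simulate_null_trait(c["ped"], c["config"], 3, kin=c["kin"])
        pd.testing.assert_frame_equal(a, b)

    def test_medication_adjustment_inverts_treatment(self, small_cohort):
        """Recorded BP + 10/5 for medicated exams restores untreated BP."""
        from pathstep import adjust_for_medication
        c = small_cohort
        cfg = c["config"]
        df = simulate_phenotypes(c["ped"], c["genotypes"], c["catalog"],
                                 cfg, 0, kin=c["kin"])
        adj = adjust_for_medication(df)
        on = df["med"] == 1
        assert on.any()
        # adjusted values are the generator's untreated values: all
        # medicated exams must satisfy the hypertension rule
        assert ((adj.loc[on, "SBP"] >= cfg.hypertension_sbp)
                | (adj.loc[on, "DBP"] >= cfg.hypertension_dbp)).all()
        off = ~on
        assert ((adj.loc[off, "SBP"] < cfg.hypertension_sbp)
                & (adj.loc[off, "DBP"] < cfg.hypertension_dbp)).all()

    def test_sibling_covariance_matches_polygenic_share(self):
        """cov(MAP_sib1, MAP_sib2) ~ sigma2_poly / 2 across replicates."""
        cfg = CohortConfig(
            seed=10, n_families=6, n_generations=2, sibship_size=2,
            age_slope_sbp=0.0, age_slope_dbp=0.0, male_effect_sbp=0.0,
            male_effect_dbp=0.0, smoke_effect_sbp=0.0, smoke_effect_dbp=0.0,
            hypertension_sbp=1e9, hypertension_dbp=1e9)  # no treatment
        ped = simulate_pedigrees(cfg)
        kin = compute_kinship(ped)
        from pathstep import compute_map
        sib_pairs = []
        for fid in ped.families:
            sibs = [m.iid for m in ped.family_members(fid)
                    if not m.is_founder]
            sib_pairs.append((sibs[0], sibs[1]))
        n_reps = 1500
        vals = {iid: [] for pair in sib_pairs for iid in pair}
        for rep in range(n_reps):
            df = simulate_null_trait(ped, cfg, rep, kin=kin)
            mp = compute_map(df["SBP"], df["DBP"])
            per_ind = pd.Series(mp).groupby(
                df["individual_id"].to_numpy()).mean()
            for iid in vals:
                vals[iid].append(per_ind[iid])
        covs = [np.cov(vals[a], vals[b])[0, 1] for a, b in sib_pairs]
        expected = cfg.polygenic_variance / 2.0
        tot_var = (cfg.polygenic_variance + cfg.residual_variance
                   + (cfg.exam_noise_variance
                      + 5 / 9 * cfg.trait_noise_variance) / cfg.exam_count)
        se = np.sqrt((tot_var ** 2 + expected ** 2)
                     / (n_reps * len(sib_pairs)))
        assert abs(np.mean(covs) - expected) <= 3 * se

    def test_causal_effect_recovered_by_regression(self, small_cohort):
        """Regressing the trait on a causal variant's count recovers
        its effect on average across replicates."""
        c = small_cohort
        cat = c["catalog"]
        sd = c["genotypes"].counts.std(axis=0)
        j = int(np.argmax(np.abs(cat.betas) * (sd > 0.2)))
        beta_true = cat.betas[j]
        g = c["genotypes"].columns([cat.variant_ids[j]])[:, 0]
        g = g - g.mean()
        from pathstep import compute_map
        slopes = []
        for rep in range(150):
            df = simulate_phenotypes(c["ped"], c["genotypes"], cat,
                                     c["config"], rep, kin=c["kin"])
            adj_map = compute_map(df["SBP"] + 10 * df["med"],
                                  df["DBP"] + 5 * df["med"])
            per_ind = pd.Series(adj_map).groupby(
                df["individual_id"].to_numpy()).mean()
            y = per_ind[c["ped"].ids].to_numpy()
            slopes.append(float(g @ y / (g @ g)))
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        # other causal variants in LD-by-pedigree inflate the regression
        # slightly; 6 SE keeps this a real direction+magnitude check
        assert abs(np.mean(slopes) - beta_true) <= 6 * se + 0.15 * abs(beta_true)

    def test_null_trait_uncorrelated_with_genotypes(self, small_cohort):
        """After removing the fixed covariate effects (which correlate
        with pedigree structure, as does any realized gene drop), the
        null trait carries no per-variant signal across replicates."""
        c = small_cohort
        from pathstep import compute_map, prepare_analysis_table
        g = c["genotypes"].counts
        poly = g.std(axis=0) > 0
        gc = g[:, poly] - g[:, poly].mean(axis=0)
        cors = []
        for rep in range(60):
            df = simulate_null_trait(c["ped"], c["config"], rep,
                                     kin=c["kin"])
            coll = prepare_analysis_table(df).set_index("individual_id")
            coll = coll.loc[c["ped"].ids]
            X = np.column_stack([np.ones(len(coll)), coll["sex"],
                                 coll["mean_age"], coll["ever_smoked"]])
            y = coll["mean_MAP"].to_numpy()
            yc = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            cors.append(gc.T @ yc / (np.linalg.norm(gc, axis=0)
                                     * np.linalg.norm(yc)))
        cors = np.array(cors)
        t = cors.mean(axis=0) / (cors.std(axis=0, ddof=1)
                                 / np.sqrt(cors.shape[0]))
        # expectation zero for every variant; allow for the maximum over
        # ~250 dependent t statistics
        assert np.abs(t).max() < 5.0


def test_config_validation_errors():
    with pytest.raises(ConfigError):
        CohortConfig(polygenic_variance=-1).validate()
    with pytest.raises(ConfigError):
        CohortConfig(exam_count=0).validate()
    with pytest.raises(ConfigError):
        CohortConfig(n_replicates=0).validate()
    with pytest.raises(ConfigError):
        CohortConfig(sibship_kind="uniform").validate()


def test_config_dict_roundtrip():
    cfg = CohortConfig(seed=9, n_genes=12)
    assert CohortConfig.from_dict(cfg.to_dict()) == cfg
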