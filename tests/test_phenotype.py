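"""Cox fitting against independent oracles, KM/log-rank, covariate and
sex-difference maps."""

import numpy as np
import pandas as pd
import pytest

from cartograph import (SurvivalTable, ConfigurationError, cox_fit,
                        cox_partial_loglik, covariate_map,
                        female_difference_map, km_logrank, prognostic_map)


def _surv(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return SurvivalTable(pd.Index(ids), np.asarray(times, dtype=float),
                         np.asarray(events, dtype=int))


def _grid_search_beta(x, surv, ties="breslow", lo=-5, hi=5):
    """Independent oracle: maximize the partial likelihood on a grid,
    then refine by golden-section search."""
    from scipy.optimize import minimize_scalar
    grid = np.linspace(lo, hi, 2001)
    ll = [cox_partial_loglik(b, x, surv.time, surv.event, ties) for b in grid]
    b0 = grid[int(np.argmax(ll))]
    res = minimize_scalar(
        lambda b: -cox_partial_loglik(b, x, surv.time, surv.event, ties),
        bracket=(b0 - 0.01, b0, b0 + 0.01), method="brent",
        options={"xtol": 1e-12})
    return float(res.x)


FIXTURE_TOYS = [
    # (times, events, covariate)
    ([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1], [0, 1, 0, 1, 0, 1]),
    ([2, 2, 3, 5, 5, 7], [1, 0, 1, 1, 1, 0], [0.5, -1, 2, 0, 1, -0.5]),
    ([1, 1, 1, 2, 3], [1, 1, 0, 1, 1], [1, 0, 1, 0, 1]),       # heavy ties
    ([4, 3, 2, 1], [1, 1, 1, 1], [0.4, 0.1, 0.3, 0.2]),
    ([1, 2, 3, 4, 5, 6, 7, 8], [0, 1, 0, 1, 0, 1, 0, 1],
     [2, 1, 2, 1, 0, 0, -1, -1]),
]


class TestCoxFit:
    @pytest.mark.parametrize("times,events,x", FIXTURE_TOYS)
    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_newton_matches_grid_search(self, times, events, x, ties):
        surv = _surv(times, events)
        res = cox_fit(np.asarray(x, dtype=float), surv, ties=ties)
        assert res.valid
        oracle = _grid_search_beta(np.asarray(x, dtype=float), surv, ties)
        assert res.beta == pytest.approx(oracle, abs=1e-6)

    def test_efron_matches_lifelines(self):
        """Independent cross-check against lifelines (Efron ties)."""
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(1)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x))
        e = (rng.random(n) < 0.8).astype(int)
        surv = _surv(t, e)
        res = cox_fit(x, surv, ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_constant_covariate_flagged(self):
        res = cox_fit(np.ones(6), _surv([1, 2, 3, 4, 5, 6], [1] * 6))
        assert not res.valid and res.hr == 1.0

    def test_too_few_events_flagged(self):
        res = cox_fit(np.arange(4.0), _surv([1, 2, 3, 4], [1, 0, 0, 0]))
        assert not res.valid

    def test_separation_diverges_to_invalid(self):
        # perfect separation: covariate orders events exactly
        res = cox_fit(np.array([3.0, 2.0, 1.0, 0.0]),
                      _surv([1, 2, 3, 4], [1, 1, 1, 1]))
        assert not res.valid

    def test_planted_hazard_mean_recovery(self):
        """100 replicates at n=500 with true log-HR = log 2: the mean
        estimate sits in [0.60, 0.79]."""
        from cartograph import CohortConfig, generate_cohort, generate_survival
        cfg = CohortConfig(n_genes=10, n_samples=500, n_subtypes=2,
                           n_modules=1, genes_per_module=5, cpgs_per_gene=1,
                           hazard_beta=np.log(2.0), censor_rate=0.2, seed=31)
        expr, _, _, _, truth = generate_cohort(cfg)
        sub = np.array([truth.subtype_of_sample[s] for s in expr.sample_ids])
        activity = truth.module_activity(sub)[0]
        rng = np.random.default_rng(32)
        betas = []
        for _ in range(100):
            surv = generate_survival(truth, expr, cfg, rng=rng)
            res = cox_fit(activity, surv)
            assert res.valid
            betas.append(res.beta)
        assert 0.60 <= np.mean(betas) <= 0.79


class TestPrognosticMap:
    def test_null_calibration_and_permutation(self, som_expr, cohort):
        """Survival independent of the modules: ~5% of units reach
        |z| > 1.96, and the planted-free map matches a permuted one."""
        _, _, _, pheno, _ = cohort
        surv = SurvivalTable.from_phenotype(pheno)  # hazard_beta = 0
        pm = prognostic_map(som_expr, surv)
        z = pm.z[pm.valid]
        frac = np.mean(np.abs(z) > 1.96)
        assert 0.02 <= frac <= 0.09
        assert np.median(np.abs(pm.grid[pm.valid])) < 0.2

    def test_planted_adverse_module_detected(self):
        from cartograph import (CohortConfig, SomParams, center_genes,
                                generate_cohort, train_som)
        cfg = CohortConfig(n_genes=800, n_samples=200, n_subtypes=2,
                           n_modules=2, genes_per_module=40,
                           cpgs_per_gene=1, hazard_beta=np.array([np.log(3), 0.0]),
                           seed=41)
        expr, _, ann, pheno, truth = generate_cohort(cfg)
        model = train_som(center_genes(expr),
                          SomParams(grid_k=12, epochs=25, seed=41))
        surv = SurvivalTable.from_phenotype(pheno)
        pm = prognostic_map(model, surv)
        genes = truth.module_members[0]
        pos = model.gene_ids.get_indexer(pd.Index(genes))
        units = np.unique(model.bmu[pos[pos >= 0]])
        flat_lhr = pm.grid.ravel()
        flat_z = pm.z.ravel()
        background = np.setdiff1d(np.flatnonzero(pm.valid.ravel()), units)
        assert np.median(flat_lhr[units]) > 0
        assert np.median(flat_z[units]) > np.median(flat_z[background])
        # permuting survival destroys the planted signal
        rng = np.random.default_rng(42)
        perm = rng.permutation(len(surv))
        surv_perm = SurvivalTable(surv.sample_id, surv.time[perm],
                                  surv.event[perm])
        pm_perm = prognostic_map(model, surv_perm)
        assert np.median(np.abs(pm_perm.grid.ravel()[units])) < \
            np.median(np.abs(flat_lhr[units]))

    def test_insufficient_overlap_raises(self, som_expr):
        surv = _surv([1, 2], [1, 1], ids=["s0000", "s0001"])
        with pytest.raises(ConfigurationError):
            prognostic_map(som_expr, surv)


class TestKmLogrank:
    def test_identical_groups_null(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8]
        events = [1, 1, 0, 1, 1, 1, 0, 1]
        ids = [f"s{i}" for i in range(8)]
        surv = _surv(times + times, events + events,
                     ids=ids + [f"t{i}" for i in range(8)])
        curves, chi2, p = km_logrank(
            {"a": ids, "b": [f"t{i}" for i in range(8)]}, surv)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_risk_set_oracle(self):
        """Two tiny groups tabulated by hand.

        group a: (1,d) (3,d) (5,c); group b: (2,d) (4,d) (6,d)
        Risk sets / expected events for group a:
          t=1: n=6, na=3, d=1, E_a=0.5, V=0.25
          t=2: n=5, na=2, d=1, E_a=0.4, V=0.24
          t=3: n=4, na=2, d=1, E_a=0.5, V=0.25
          t=4: n=3, na=1, d=1, E_a=1/3, V=2/9
          t=6: n=1, na=0, d=1, E_a=0,   V=0
        O_a=2, E_a=1.7333.., V=0.96222.. -> chi2=(O-E)^2/V=0.0739...
        """
        surv = _surv([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 1, 1],
                     ids=["a1", "a2", "a3", "b1", "b2", "b3"])
        curves, chi2, p = km_logrank({"a": ["a1", "a2", "a3"],
                                      "b": ["b1", "b2", "b3"]}, surv)
        o_minus_e = 2 - (0.5 + 0.4 + 0.5 + 1 / 3 + 0.0)
        var = 0.25 + 0.24 + 0.25 + 2 / 9 + 0.0
        assert chi2 == pytest.approx(o_minus_e ** 2 / var, abs=1e-6)

    def test_km_curve_properties(self):
        surv = _surv([1, 2, 2, 3, 5], [1, 1, 0, 1, 1],
                     ids=[f"s{i}" for i in range(5)])
        curves, _, _ = km_logrank(
            {"a": [f"s{i}" for i in range(5)], "b": [f"s{i}" for i in range(5)]},
            surv)
        km = curves["a"]["survival"].to_numpy()
        assert km[0] == 1.0
        assert np.all(np.diff(km) <= 1e-12)
        # hand product-limit: t=1 4/5; t=2 (d=1,n=4) *3/4; t=3 (n=2) *1/2; t=5 0
        assert curves["a"].set_index("time")["survival"].loc[3.0] == \
            pytest.approx(0.8 * 0.75 * 0.5)

    def test_empty_group_raises(self):
        surv = _surv([1, 2], [1, 1])
        with pytest.raises(ConfigurationError):
            km_logrank({"a": ["s0", "s1"], "b": []}, surv)


class TestCovariateMap:
    def test_exact_correlation_with_own_metagene(self, som_expr):
        u = 17
        x = pd.Series(som_expr.codebook[u], index=som_expr.sample_ids)
        cm = covariate_map(som_expr, x)
        assert cm.grid.ravel()[u] == pytest.approx(1.0)
        cm_neg = covariate_map(som_expr, -x)
        assert cm_neg.grid.ravel()[u] == pytest.approx(-1.0)

    def test_null_scaling_of_mean_abs_r(self, som_expr):
        """Independent noise covariate: mean |r| tracks sqrt(2/(pi*n))."""
        rng = np.random.default_rng(55)
        n = len(som_expr.sample_ids)
        vals = []
        for _ in range(20):
            x = pd.Series(rng.normal(size=n), index=som_expr.sample_ids)
            cm = covariate_map(som_expr, x)
            vals.append(np.mean(np.abs(cm.grid[cm.valid])))
        expected = np.sqrt(2.0 / (np.pi * n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.25)

    def test_constant_covariate_all_invalid(self, som_expr):
        x = pd.Series(1.0, index=som_expr.sample_ids)
        cm = covariate_map(som_expr, x)
        assert not cm.valid.any()


class TestFemaleDifferenceMap:
    def test_zero_when_selection_matches_population(self):
        # sex alternates and metagene is sex-independent by symmetry
        from cartograph import SomParams, train_som, OmicsMatrix
        rng = np.random.default_rng(6)
        values = rng.normal(size=(60, 16))
        m = OmicsMatrix(pd.DataFrame(
            values - values.mean(axis=1, keepdims=True),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{j}" for j in range(16)]), "centered")
        model = train_som(m, SomParams(grid_k=4, epochs=8))
        sex = pd.Series(["F", "M"] * 8, index=model.sample_ids)
        fm = female_difference_map(model, sex)
        assert fm.valid.any()
        # permutation null: scores center on zero
        scores = []
        rng2 = np.random.default_rng(7)
        for _ in range(100):
            perm = pd.Series(rng2.permutation(sex.to_numpy()),
                             index=sex.index)
            fperm = female_difference_map(model, perm)
            scores.append(fperm.grid[fperm.valid].mean())
        assert abs(np.mean(scores)) < 15.0

    def test_female_only_module_scores_positive(self):
        from cartograph import (CohortConfig, SomParams, center_genes,
                                generate_cohort, train_som)
        cfg = CohortConfig(n_genes=400, n_samples=80, n_subtypes=2,
                           n_modules=1, genes_per_module=30, cpgs_per_gene=1,
                           noise_sd_expr=0.15, seed=61)
        expr, _, _, pheno, truth = generate_cohort(cfg)
        # declare subtype-0 samples female: the module is female-specific
        sub = np.array([truth.subtype_of_sample[s] for s in expr.sample_ids])
        sex = pd.Series(np.where(sub == 0, "F", "M"), index=expr.sample_ids)
        model = train_som(center_genes(expr),
                          SomParams(grid_k=10, epochs=20, seed=61))
        fm = female_difference_map(model, sex)
        genes = truth.module_members[0]
        pos = model.gene_ids.get_indexer(pd.Index(genes))
        units = np.unique(model.bmu[pos[pos >= 0]])
        assert (fm.grid.ravel()[units] > 0).all()

    def test_single_sex_raises(self, som_expr):
        sex = pd.Series("F", index=som_expr.sample_ids)
        with pytest.raises(ConfigurationError):
            female_difference_map(som_expr, sex)


def test_sex_filter_removes_chrx_artifact():
    """A chrX-linked sex-biased gene block inflates the female-difference
    map only when sex chromosomes are kept."""
    from cartograph import (OmicsMatrix, SomParams, center_genes,
                            drop_sex_chromosomes, train_som)
    rng = np.random.default_rng(71)
    n_genes, n_samples = 300, 80
    sex = np.array(["F", "M"] * (n_samples // 2))
    values = rng.normal(0, 0.25, size=(n_genes, n_samples))
    values[:40][:, sex == "F"] += 1.0  # chrX block expressed in females
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    ann = pd.DataFrame({
        "gene_id": genes,
        "chromosome": ["chrX"] * 40 + ["chr1"] * (n_genes - 40),
        "tss": 1000, "strand": "+"})
    m = OmicsMatrix(pd.DataFrame(values, index=genes, columns=samples))
    sex_s = pd.Series(sex, index=samples)
    params = SomParams(grid_k=8, epochs=15, seed=71)
    with_x = train_som(center_genes(m), params)
    without_x = train_som(center_genes(drop_sex_chromosomes(m, ann)), params)
    fm_with = female_difference_map(with_x, sex_s)
    fm_without = female_difference_map(without_x, sex_s)
    assert np.abs(fm_with.grid[fm_with.valid]).mean() > \
        1.5 * np.abs(fm_without.grid[fm_without.valid]).mean()
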