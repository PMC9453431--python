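"""Williams trend gating, model fitting, selection and BMC estimation."""

import numpy as np
import pandas as pd
import pytest

import phenanchor as pa
from phenanchor.bmc import (
    BmcConfig,
    compute_bmc,
    fit_all_families,
    fit_family,
    gene_bmc_table,
    geneset_bmc,
    predict,
    select_model,
    williams_trend,
    williams_trend_matrix,
)
from phenanchor.datatypes import DoseResponseFitRecord
from phenanchor.dge import filter_low_counts, normalize_counts

DOSES = np.repeat([0.0, 0.205, 0.512, 1.28, 3.2, 8.0, 20.0, 50.0], 4)
FAST = BmcConfig(n_permutations=500)


def _expr_frame(rows, design):
    return pd.DataFrame(rows, columns=design.sample_ids)


class TestWilliamsTrend:
    def test_constant_expression_not_significant(self, design32):
        e = _expr_frame(np.ones((1, 32)), design32)
        e.index = ["flat"]
        res = williams_trend(e.iloc[0], design32, FAST, seed=0)
        assert res.p >= FAST.trend_alpha and not res.passes

    def test_clean_monotone_signal_hits_permutation_floor(self, design32):
        rng = np.random.default_rng(0)
        conc = design32.concentration_of().loc[design32.sample_ids].to_numpy()
        y = np.argsort(np.argsort(conc)).astype(float) + rng.normal(0, 1e-3, 32)
        e = _expr_frame(y[None, :], design32)
        e.index = ["mono"]
        res = williams_trend(e.iloc[0], design32, FAST, seed=1)
        assert res.p <= 2.0 / (FAST.n_permutations + 1) + 1e-12
        assert res.direction == "up" and res.passes

    def test_decreasing_signal_detected_down(self, design32):
        rng = np.random.default_rng(2)
        conc = design32.concentration_of().loc[design32.sample_ids].to_numpy()
        y = -np.sqrt(conc) + rng.normal(0, 0.05, 32)
        e = _expr_frame(y[None, :], design32)
        e.index = ["dec"]
        res = williams_trend(e.iloc[0], design32, FAST, seed=1)
        assert res.direction == "down" and res.passes

    def test_type_i_error_calibrated(self, null_dataset):
        norm = normalize_counts(filter_low_counts(null_dataset.counts))
        log_expr = np.log2(norm + 1.0)
        cfg = BmcConfig(n_permutations=1000)
        res = williams_trend_matrix(log_expr, null_dataset.design, cfg, seed=3)
        assert len(res) >= 2000
        rate = (res["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_negation_symmetry(self, design32):
        rng = np.random.default_rng(5)
        conc = design32.concentration_of().loc[design32.sample_ids].to_numpy()
        y = 3 * conc / (10 + conc) + rng.normal(0, 0.2, 32)
        up = _expr_frame(y[None, :], design32)
        up.index = ["g"]
        down = -up
        r_up = williams_trend_matrix(up, design32, FAST, seed=9).iloc[0]
        r_down = williams_trend_matrix(down, design32, FAST, seed=9).iloc[0]
        assert abs(r_up["statistic"]) == pytest.approx(abs(r_down["statistic"]), rel=1e-12)
        assert r_up["p"] == pytest.approx(r_down["p"])
        assert {r_up["direction"], r_down["direction"]} == {"up", "down"}


class TestFitFamily:
    def test_linear_on_noiseless_linear_data(self):
        y = 2.0 + 0.3 * DOSES
        rec = fit_family(DOSES, y, "linear")
        assert rec.converged
        assert rec.params["b1"] == pytest.approx(0.3, rel=1e-9)
        assert rec.gof_p == pytest.approx(1.0)

    def test_hill_parameter_recovery(self):
        rng = np.random.default_rng(4)
        y = 1.0 + 8.0 * DOSES**2 / (5.0**2 + DOSES**2) + rng.normal(0, 0.1, len(DOSES))
        rec = fit_family(DOSES, y, "hill")
        assert rec.params["v"] == pytest.approx(8.0, rel=0.15)
        assert rec.params["k"] == pytest.approx(5.0, rel=0.15)

    def test_aic_penalizes_overparameterized_model(self):
        rng = np.random.default_rng(8)
        y = 1.0 + 0.2 * DOSES + rng.normal(0, 0.3, len(DOSES))
        lin = fit_family(DOSES, y, "linear")
        p2 = fit_family(DOSES, y, "poly2")
        assert lin.aic < p2.aic

    def test_all_families_converge_on_saturating_signal(self):
        rng = np.random.default_rng(11)
        y = 5.0 + 4.0 * DOSES / (8.0 + DOSES) + rng.normal(0, 0.2, len(DOSES))
        fits = fit_all_families(DOSES, y)
        assert sum(np.isfinite(f.aic) for f in fits) >= 8


class TestSelectModel:
    def _hill(self, k, aic=10.0, gof=0.5):
        r = DoseResponseFitRecord("g", "hill", {"g": 0, "v": 1, "k": k, "n": 2}, aic=aic, gof_p=gof)
        return r

    def _lin(self, aic, gof=0.5):
        return DoseResponseFitRecord("g", "linear", {"b0": 0, "b1": 1}, aic=aic, gof_p=gof)

    def test_hill_k_below_one_third_lowest_dose_flagged(self):
        # 0.05 < 0.205/3 = 0.0683: flag and fall through to next model
        sel = select_model([self._hill(0.05, aic=5.0), self._lin(aic=7.0)], 0.205)
        assert sel.family == "linear" and sel.selected

    def test_hill_k_above_threshold_not_flagged(self):
        sel = select_model([self._hill(0.3, aic=5.0), self._lin(aic=7.0)], 0.205)
        assert sel.family == "hill" and not sel.hill_flagged

    def test_lowest_aic_wins(self):
        sel = select_model([self._lin(10.0), DoseResponseFitRecord("g", "poly2", {}, aic=12.0)], 0.205)
        assert sel.aic == 10.0

    def test_flagged_hill_returned_when_no_alternative_fits(self):
        sel = select_model([self._hill(0.01, aic=5.0), self._lin(aic=7.0, gof=0.001)], 0.205)
        assert sel.family == "hill" and sel.hill_flagged


class TestComputeBmc:
    def test_linear_closed_form(self):
        y = 1.0 + 2.0 * DOSES
        rec = fit_family(DOSES, y, "linear")
        rec = compute_bmc(rec, control_sd=1.0, max_dose=50.0, n_boot=0)
        assert rec.bmc == pytest.approx(1.349 / 2.0, rel=1e-6)

    def test_flat_curve_removed_above_max(self):
        rng = np.random.default_rng(1)
        y = 5.0 + rng.normal(0, 1e-6, len(DOSES))
        rec = fit_family(DOSES, y, "linear")
        rec = compute_bmc(rec, control_sd=1.0, max_dose=50.0, n_boot=0)
        assert rec.removed_above_max and rec.bmc is None

    def test_steep_hill_bmc_below_ec50_matches_grid(self):
        rng = np.random.default_rng(3)
        y = 2.0 + 9.0 * DOSES**2 / (25.0 + DOSES**2) + rng.normal(0, 0.1, len(DOSES))
        rec = fit_family(DOSES, y, "hill")
        rec = compute_bmc(rec, control_sd=rec.residual_sd, max_dose=50.0, n_boot=0)
        assert rec.bmc < 5.0
        grid = np.linspace(1e-6, 50.0, 10**5)
        f0 = predict(rec, 0.0)
        target = 1.349 * rec.residual_sd
        hit = np.nonzero(np.abs(predict(rec, grid) - f0) >= target)[0]
        assert rec.bmc == pytest.approx(grid[hit[0]], rel=0.01)

    def test_bootstrap_interval_orders_and_covers(self):
        # bmdl <= bmc <= bmdu on every run, and the interval covers the true
        # BMC in most resimulations
        cfg = BmcConfig()
        true_sigma = 0.3
        truth = lambda d: 5.0 + 6.0 * d**2 / (15.0**2 + d**2)
        # true BMC solves 6 d^2/(225+d^2) = 1.349*sigma
        x = 1.349 * true_sigma / 6.0
        true_bmc = 15.0 * np.sqrt(x / (1.0 - x))
        covered, n_ok = 0, 0
        for seed in range(30):
            rng = np.random.default_rng(500 + seed)
            y = truth(DOSES) + rng.normal(0, true_sigma, len(DOSES))
            fits = fit_all_families(DOSES, y, cfg)
            sel = select_model(fits, 0.205, cfg)
            cand = [f.family for f in fits if np.isfinite(f.aic) and f.aic <= sel.aic + 10]
            sel = compute_bmc(
                sel, sel.pooled_sd, cfg, 50.0, n_boot=80, seed=seed,
                candidate_families=cand, lowest_positive_dose=0.205,
            )
            if sel.bmc is None or sel.bmdl is None or sel.bmdu is None:
                continue
            assert sel.bmdl <= sel.bmc <= sel.bmdu
            n_ok += 1
            covered += sel.bmdl <= true_bmc <= sel.bmdu
        assert n_ok >= 25
        assert covered / n_ok >= 0.85


class TestGenesetBmc:
    def _rec(self, gid, bmc):
        r = DoseResponseFitRecord(gid, "linear", aic=1.0)
        r.bmc = bmc
        r.removed_above_max = bmc is None
        return r

    def test_median_of_defined_bmcs(self):
        recs = [self._rec("a", 2.0), self._rec("b", 5.0), self._rec("c", 8.0)]
        out = geneset_bmc(recs, {"a", "b", "c"})
        assert out["median_bmc"] == 5.0 and out["n_modeled"] == 3

    def test_all_removed_gives_undefined(self):
        recs = [self._rec("a", None)]
        with pytest.warns(UserWarning):
            out = geneset_bmc(recs, {"a"})
        assert out["median_bmc"] is None and out["n_modeled"] == 0


class TestPipelineTable:
    def test_failing_genes_never_fitted_and_symmetry(self, small_dataset):
        ds = small_dataset
        norm = normalize_counts(filter_low_counts(ds.counts))
        log_expr = np.log2(norm + 1.0)
        cfg = BmcConfig(n_permutations=300)
        table, _ = gene_bmc_table(log_expr, ds.design, cfg, seed=2)
        gated = table[~table["trend_passes"]]
        assert gated["family"].isna().all()
        passing = table[table["trend_passes"]]
        assert passing["family"].notna().all()
        # negating all responses leaves |statistic| and bmc unchanged
        sub = log_expr.loc[passing.index[:5]]
        t_pos, _ = gene_bmc_table(sub, ds.design, cfg, seed=2)
        t_neg, _ = gene_bmc_table(-sub, ds.design, cfg, seed=2)
        assert np.allclose(
            np.abs(t_pos["trend_statistic"]), np.abs(t_neg["trend_statistic"])
        )
        both = t_pos["bmc"].notna() & t_neg["bmc"].notna()
        assert np.allclose(t_pos.loc[both, "bmc"], t_neg.loc[both, "bmc"], rtol=0.05)

    def test_module_median_bmc_recovers_truth_oracle(self, small_dataset):
        # independent oracle: per-gene true BMC solves
        # emax d^n/(ec50^n+d^n) = 1.349 * sigma_g, with sigma_g the log2
        # noise SD implied by the generator (NB sampling noise plus the
        # shared module latent deviate)
        ds = small_dataset
        module = [t for t in ds.truths if t.klass == "ahr_module"]
        ln2 = np.log(2.0)
        vbar = np.mean([(1 / t.baseline_mean + t.dispersion) / ln2**2 for t in module])
        rho = 0.6
        var_latent = rho / (1 - rho) * vbar
        true_bmcs = []
        for t in module:
            sigma = np.sqrt((1 / t.baseline_mean + t.dispersion) / ln2**2 + var_latent)
            x = 1.349 * sigma / abs(t.emax)
            if x >= 1:
                continue
            true_bmcs.append(t.ec50 * (x / (1 - x)) ** (1 / t.hill_n))
        target = float(np.median(true_bmcs))

        norm = normalize_counts(filter_low_counts(ds.counts))
        log_expr = np.log2(norm + 1.0)
        cfg = BmcConfig(n_permutations=300)
        gene_ids = [t.gene_id for t in module]
        table, recs = gene_bmc_table(log_expr, ds.design, cfg, seed=4, genes=gene_ids)
        out = geneset_bmc(recs, set(gene_ids))
        assert out["n_modeled"] >= 10
        assert abs(out["median_bmc"] - target) / target < 0.30
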