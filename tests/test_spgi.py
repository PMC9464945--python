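import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import epmkit as ek


def _cohort(seed=40, n_per=12, k=4, n_genes=30, step=2.0):
    """log2-scale expression with k clusters; first 3 genes graded across clusters."""
    rng = np.random.default_rng(seed)
    cols = [f"s{c}_{i}" for c in range(k) for i in range(n_per)]
    labels = pd.Series([c for c in range(k) for _ in range(n_per)], index=cols)
    base = rng.uniform(3, 9, n_genes)
    vals = base[:, None] + rng.normal(0, 0.3, (n_genes, len(cols)))
    for g in range(3):
        grades = rng.permutation(k) * step
        vals[g] += labels.map(dict(enumerate(grades))).to_numpy()
    expr = pd.DataFrame(vals, index=[f"g{i:02d}" for i in range(n_genes)], columns=cols)
    return expr, labels


class TestPairwiseDegs:
    def test_identical_gene_not_deg_and_shifted_gene_is(self):
        rng = np.random.default_rng(41)
        cols = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        labels = pd.Series([0] * 10 + [1] * 10, index=cols)
        flat = np.full(20, 5.0) + rng.normal(0, 0.05, 20)
        shifted = np.concatenate([np.full(10, 2.0), np.full(10, 6.0)]) + rng.normal(
            0, 0.05, 20
        )
        expr = pd.DataFrame([flat, flat + 0, shifted], index=["flat", "flat2", "up"],
                            columns=cols)
        # needs >= 3 samples per cluster and 2 clusters -> single pair
        degs = ek.pairwise_degs(expr, labels, fdr=0.05, min_abs_log2fc=1.0)
        table = degs[(0, 1)]
        assert not table.loc["flat", "deg"]
        assert table.loc["up", "deg"]
        assert table.loc["up", "log2fc"] == pytest.approx(-4.0, abs=0.1)

    def test_planted_recall_and_fdr(self):
        for seed in range(5):
            rng = np.random.default_rng(500 + seed)
            n_per = 10
            cols = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
            labels = pd.Series([0] * n_per + [1] * n_per, index=cols)
            n_deg, n_null = 100, 400
            vals = rng.normal(6, 0.5, (n_deg + n_null, 2 * n_per))
            vals[:n_deg, n_per:] += rng.choice([-1, 1], n_deg)[:, None] * 3.0
            expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_deg + n_null)],
                                columns=cols)
            table = ek.pairwise_degs(expr, labels)[(0, 1)]
            called = set(table.index[table["deg"]])
            truth = {f"g{i}" for i in range(n_deg)}
            recall = len(called & truth) / n_deg
            fdr = len(called - truth) / max(len(called), 1)
            assert recall >= 0.9
            assert fdr <= 0.1

    def test_small_cluster_is_error(self):
        expr, labels = _cohort()
        labels.iloc[:10] = 9  # cluster 9 has 10, cluster 0 drops to 2
        with pytest.raises(ValueError, match="fewer than 3"):
            ek.pairwise_degs(expr, labels)


class TestRecurrentDegs:
    def test_counting_against_brute_force(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(50)]
        pairs = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        lists = {}
        member = rng.random((50, len(pairs))) < 0.5
        for j, pair in enumerate(pairs):
            lists[pair] = pd.DataFrame({"deg": member[:, j]}, index=genes)
        out = ek.recurrent_degs(lists, min_occurrences=4)
        expected = [g for i, g in enumerate(genes) if member[i].sum() >= 4]
        assert out == sorted(expected)

    def test_boundary_membership(self):
        genes = ["keep", "drop"]
        lists = {}
        for j in range(6):
            lists[(0, j + 1)] = pd.DataFrame(
                {"deg": [True, j < 3]}, index=genes
            )  # keep: 6/6, drop: 3/6
        out = ek.recurrent_degs(lists, 4)
        assert out == ["keep"]

    def test_too_few_pairs_is_error(self):
        lists = {(0, 1): pd.DataFrame({"deg": [True]}, index=["g"])}
        with pytest.raises(ValueError):
            ek.recurrent_degs(lists, 4)


def _survival_for(expr, betas, seed, censor_rate=0.3):
    rng = np.random.default_rng(seed)
    lp = np.zeros(expr.shape[1])
    for g, b in betas.items():
        x = expr.loc[g]
        lp += b * ((x - x.mean()) / x.std(ddof=1)).to_numpy()
    t = rng.exponential(1.0, expr.shape[1]) / (0.002 * np.exp(lp))
    if censor_rate:
        c = rng.uniform(0, np.quantile(t, 1.3 * (1 - censor_rate)), expr.shape[1])
        return pd.DataFrame(
            {"time": np.minimum(t, c), "event": (t <= c).astype(int)}, index=expr.columns
        )
    return pd.DataFrame({"time": t, "event": 1}, index=expr.columns)


class TestCoxScreen:
    def test_prognostic_gene_retained_with_hr_direction(self):
        rng = np.random.default_rng(43)
        expr = pd.DataFrame(
            rng.normal(6, 1, (5, 200)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(200)],
        )
        surv = _survival_for(expr, {"g0": 1.0}, seed=44)
        table = ek.cox_screen(expr, surv, [f"g{i}" for i in range(5)])
        assert table.loc["g0", "prognostic"]
        assert table.loc["g0", "hr"] > 1

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(45)
        expr = pd.DataFrame(
            np.vstack([np.full(60, 3.0), rng.normal(5, 1, 60)]),
            index=["const", "ok"], columns=[f"s{i}" for i in range(60)],
        )
        surv = _survival_for(expr, {}, seed=46)
        with pytest.warns(UserWarning, match="constant"):
            table = ek.cox_screen(expr, surv, ["const", "ok"])
        assert "const" not in table.index

    def test_too_few_events_is_error(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(5, 1, (2, 20)),
                            index=["a", "b"], columns=[f"s{i}" for i in range(20)])
        surv = pd.DataFrame({"time": np.arange(20) + 1.0, "event": [1] * 5 + [0] * 15},
                            index=expr.columns)
        with pytest.raises(ValueError, match="at least 10 events"):
            ek.cox_screen(expr, surv, ["a", "b"])


class TestLassoCox:
    def _planted(self, seed):
        rng = np.random.default_rng(seed)
        n, n_genes = 300, 50
        expr = pd.DataFrame(
            rng.normal(6, 1, (n_genes, n)),
            index=[f"g{i:02d}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n)],
        )
        betas = {"g00": 1.0, "g01": -1.0, "g02": 1.0, "g03": -1.0, "g04": 1.0}
        surv = _survival_for(expr, betas, seed=seed + 1)
        return expr, surv, betas

    def test_planted_recovery_with_signs(self):
        hits = []
        for seed in range(5):
            expr, surv, betas = self._planted(600 + seed)
            model = ek.lasso_cox_fit(expr, surv, list(expr.index), seed=seed)
            found = [g for g in betas if g in model.genes]
            hits.append(len(found))
            for g in found:
                assert np.sign(model.coefficients[g]) == np.sign(betas[g])
        assert min(hits) >= 4

    def test_single_strong_gene_dominates(self):
        rng = np.random.default_rng(47)
        expr = pd.DataFrame(
            rng.normal(6, 1, (20, 250)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(250)],
        )
        surv = _survival_for(expr, {"g0": 1.2}, seed=48)
        model = ek.lasso_cox_fit(expr, surv, list(expr.index), seed=1)
        assert "g0" in model.genes
        assert model.coefficients.abs().idxmax() == "g0"

    def test_penalty_limit_empties_model_on_path(self):
        expr, surv, _ = self._planted(700)
        model = ek.lasso_cox_fit(expr, surv, list(expr.index), seed=2)
        # largest penalty on the descending path keeps (near) zero genes
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        z = ((expr.T - expr.T.mean()) / expr.T.std(ddof=1)).to_numpy()
        y = Surv.from_arrays(event=surv["event"].astype(bool), time=surv["time"])
        fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[model.cv_alphas[0]]).fit(z, y)
        assert (fit.coef_ == 0).all()

    def test_determinism(self):
        expr, surv, _ = self._planted(800)
        m1 = ek.lasso_cox_fit(expr, surv, list(expr.index), seed=3)
        m2 = ek.lasso_cox_fit(expr, surv, list(expr.index), seed=3)
        assert m1.genes == m2.genes
        assert np.allclose(m1.coefficients, m2.coefficients)
        assert m1.cutoff == m2.cutoff


class TestScoring:
    def _model(self):
        genes = ("gA", "gB")
        coef = pd.Series([1.0, -0.5], index=list(genes))
        return ek.SPGIModel(
            genes=genes, coefficients=coef,
            train_mean=pd.Series([0.0, 0.0], index=list(genes)),
            train_sd=pd.Series([1.0, 1.0], index=list(genes)),
            cutoff=0.5, cv_alphas=np.array([1.0]), cv_deviance=np.array([0.0]),
            alpha=1.0, seed=0,
        )

    def test_linear_arithmetic(self):
        model = self._model()
        expr = pd.DataFrame({"s1": [2.0, 2.0], "s2": [0.0, 0.0]}, index=["gA", "gB"])
        out = ek.spgi_score(model, expr)
        assert out.loc["s1", "score"] == pytest.approx(1.0)
        assert out.loc["s2", "score"] == pytest.approx(0.0)
        assert bool(out.loc["s1", "high_risk"]) and not out.loc["s2", "high_risk"]

    def test_missing_gene_named(self):
        model = self._model()
        expr = pd.DataFrame({"s1": [1.0]}, index=["gA"])
        with pytest.raises(KeyError, match="gB"):
            ek.spgi_score(model, expr)

    def test_affine_equivariance(self):
        model = self._model()
        rng = np.random.default_rng(49)
        expr = pd.DataFrame(rng.normal(5, 1, (2, 30)), index=["gA", "gB"],
                            columns=[f"s{i}" for i in range(30)])
        s0 = ek.spgi_score(model, expr)["score"]
        shifted = expr.copy()
        shifted.loc["gA"] += 3.0
        s1 = ek.spgi_score(model, shifted)["score"]
        assert np.allclose(s1 - s0, model.raw_coefficients["gA"] * 3.0)

    def test_training_median_splits_cohort(self):
        expr, surv, _ = TestLassoCox()._planted(900)
        model = ek.lasso_cox_fit(expr, surv, list(expr.index), seed=4)
        out = ek.spgi_score(model, expr)
        assert out["high_risk"].sum() <= int(np.ceil(expr.shape[1] / 2))


class TestEvaluate:
    def test_perfect_ranking_concordance(self):
        rng = np.random.default_rng(50)
        t = rng.uniform(10, 1000, 80)
        surv = pd.DataFrame({"time": t, "event": 1}, index=[f"s{i}" for i in range(80)])
        scores = pd.Series(-t, index=surv.index)
        strata = scores > scores.median()
        rep = ek.evaluate_prognosis(scores, strata, surv)
        assert rep["concordance"] == pytest.approx(1.0)

    def test_null_logrank_p_uniform(self):
        rng = np.random.default_rng(51)
        ps = []
        for _ in range(200):
            t = rng.exponential(300, 60)
            surv = pd.DataFrame({"time": t, "event": 1},
                                index=[f"s{i}" for i in range(60)])
            strata = pd.Series(rng.random(60) < 0.5, index=surv.index)
            if strata.sum() in (0, 60):
                continue
            scores = pd.Series(rng.normal(size=60), index=surv.index)
            rep = ek.evaluate_prognosis(scores, strata, surv)
            ps.append(rep["logrank_p"])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_planted_hazard_ratio_power(self):
        rng = np.random.default_rng(52)
        rejections = 0
        for _ in range(100):
            t_hi = rng.exponential(150, 150)
            t_lo = rng.exponential(300, 150)
            surv = pd.DataFrame(
                {"time": np.concatenate([t_hi, t_lo]), "event": 1},
                index=[f"s{i}" for i in range(300)],
            )
            strata = pd.Series([True] * 150 + [False] * 150, index=surv.index)
            scores = pd.Series(strata.astype(float), index=surv.index)
            rep = ek.evaluate_prognosis(scores, strata, surv)
            rejections += rep["logrank_p"] < 0.01
        assert rejections >= 95

    def test_horizon_beyond_followup_undefined(self):
        rng = np.random.default_rng(53)
        t = rng.uniform(10, 200, 40)  # well under one year
        surv = pd.DataFrame({"time": t, "event": 1}, index=[f"s{i}" for i in range(40)])
        scores = pd.Series(rng.normal(size=40), index=surv.index)
        rep = ek.evaluate_prognosis(scores, scores > scores.median(), surv)
        assert rep["auc_1y"] is None
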