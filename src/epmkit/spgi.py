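"""SPGIScore: a LASSO-Cox prognostic signature built from cluster-wise DEGs.

The funnel mirrors the cluster-characterization workflow: pairwise
differential expression among the perturbation-based clusters, restriction to
genes recurrent in at least four pairwise comparisons, a univariate Cox
screen (p < 0.05), and an L1-penalized Cox fit with the penalty chosen by
10-fold cross-validated partial-likelihood deviance. The score of a sample is
the linear predictor

    SPGIScore = sum_i Coef_i * x_i

over the LASSO-surviving genes, dichotomized at the training-cohort median.

Expression for testing, Cox screening, and the penalized fit is expected on
the log2(x+1) scale (see :func:`log2p`); genes are standardized internally
for the penalty path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from scipy.stats import ttest_ind
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

DAYS_PER_YEAR = 365.25


def log2p(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) transform of a nonnegative expression matrix."""
    return np.log2(expr + 1.0)


def _check_survival(survival: pd.DataFrame) -> pd.DataFrame:
    if not {"time", "event"} <= set(survival.columns):
        raise ValueError("survival table needs 'time' and 'event' columns")
    if (survival["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    if not survival["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return survival


def pairwise_degs(
    log2_expr: pd.DataFrame,
    labels: pd.Series,
    fdr: float = 0.05,
    min_abs_log2fc: float = 1.0,
) -> dict[tuple, pd.DataFrame]:
    """Welch t-test DEGs for every unordered cluster pair.

    Per gene and pair: Welch t on log2(x+1) values, BH adjustment within the
    pair, DEG iff q < ``fdr`` and |log2 fold change| > ``min_abs_log2fc``.
    Returns one table per pair with columns t, p, q, log2fc, deg.
    """
    from statsmodels.stats.multitest import multipletests

    labels = labels.reindex(log2_expr.columns)
    if labels.isna().any():
        raise ValueError("labels must cover all samples")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    for c in clusters:
        if (labels == c).sum() < 3:
            raise ValueError(f"cluster {c} has fewer than 3 samples")
    out: dict[tuple, pd.DataFrame] = {}
    for c1, c2 in combinations(clusters, 2):
        a = log2_expr.loc[:, labels == c1].to_numpy(dtype=float)
        b = log2_expr.loc[:, labels == c2].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = ttest_ind(a, b, axis=1, equal_var=False)
        lfc = a.mean(axis=1) - b.mean(axis=1)
        p = np.where(np.isnan(p), 1.0, p)  # constant-in-both genes: no evidence
        q = multipletests(p, method="fdr_bh")[1]
        table = pd.DataFrame(
            {"t": t, "p": p, "q": q, "log2fc": lfc}, index=log2_expr.index
        )
        table["deg"] = (table["q"] < fdr) & (table["log2fc"].abs() > min_abs_log2fc)
        out[(c1, c2)] = table
    return out


def recurrent_degs(deg_lists: dict[tuple, pd.DataFrame], min_occurrences: int = 4) -> list[str]:
    """Genes flagged as DEG in at least ``min_occurrences`` pairwise comparisons."""
    if len(deg_lists) < min_occurrences:
        raise ValueError(
            f"only {len(deg_lists)} pairwise comparisons available; "
            f"min_occurrences={min_occurrences} cannot be met"
        )
    counts: pd.Series | None = None
    for table in deg_lists.values():
        flags = table["deg"].astype(int)
        counts = flags if counts is None else counts.add(flags, fill_value=0)
    assert counts is not None
    return sorted(counts.index[counts >= min_occurrences])


def cox_screen(
    log2_expr: pd.DataFrame,
    survival: pd.DataFrame,
    genes: list[str],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox proportional-hazards screen (Efron ties, Wald p).

    One fit per gene; genes with p < ``p_threshold`` are flagged prognostic.
    Constant or non-converging genes are dropped with a warning, never an
    exception. Returns a table with coef, hr, p, prognostic.
    """
    _check_survival(survival)
    survival = survival.loc[log2_expr.columns]
    if survival["event"].sum() < 10:
        raise ValueError("Cox screen needs at least 10 events")
    rows = []
    for gene in genes:
        x = log2_expr.loc[gene]
        if x.std(ddof=0) == 0:
            warnings.warn(f"gene {gene} is constant; dropped from the Cox screen")
            continue
        df = pd.DataFrame({"time": survival["time"], "event": survival["event"], "x": x})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError):
            warnings.warn(f"Cox fit failed to converge for gene {gene}; dropped")
            continue
        coef = float(cph.params_["x"])
        p = float(cph.summary.loc["x", "p"])
        rows.append({"gene": gene, "coef": coef, "hr": float(np.exp(coef)), "p": p})
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["coef", "hr", "p"]
    )
    if len(table):
        table["prognostic"] = table["p"] < p_threshold
    return table


@dataclass(frozen=True)
class SPGIModel:
    """LASSO-surviving genes, their coefficients, and the median-score cutoff.

    ``coefficients`` are on the standardized (per-gene z) scale as fitted;
    ``raw_coefficients`` (= coef / training SD) act on the log2(x+1)
    expression scale, so score = sum raw_coef_i * x_i + const and adding c to
    one gene's expression shifts every score by raw_coef * c exactly.
    """

    genes: tuple[str, ...]
    coefficients: pd.Series
    train_mean: pd.Series
    train_sd: pd.Series
    cutoff: float
    cv_alphas: np.ndarray
    cv_deviance: np.ndarray
    alpha: float
    seed: int

    @property
    def raw_coefficients(self) -> pd.Series:
        return self.coefficients / self.train_sd

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "coefficients": self.coefficients.round(12).to_dict(),
            "raw_coefficients": self.raw_coefficients.round(12).to_dict(),
            "train_mean": self.train_mean.round(12).to_dict(),
            "train_sd": self.train_sd.round(12).to_dict(),
            "cutoff": round(float(self.cutoff), 12),
            "alpha": float(self.alpha),
            "seed": self.seed,
        }


def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow-approximation Cox partial log-likelihood of a linear predictor."""
    order = np.argsort(-time, kind="stable")  # descending time
    lp, time, event = lp[order], time[order], event[order]
    log_cumsum = np.logaddexp.accumulate(lp)
    # risk set for an event at t = all samples with time >= t; with descending
    # sort, that is the running prefix up to the last index sharing this time
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        denom = log_cumsum[j]
        for k in range(i, j + 1):
            if event[k]:
                ll += lp[k] - denom
        i = j + 1
    return float(ll)


def lasso_cox_fit(
    log2_expr: pd.DataFrame,
    survival: pd.DataFrame,
    genes: list[str],
    n_folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
) -> SPGIModel:
    """L1-penalized Cox fit with the penalty chosen by cross-validated deviance.

    Genes are standardized on the training data; the descending alpha path is
    laid out on the full data, and for each fold the held-out deviance
    -2 * loglik(test linear predictor) is averaged. The model keeps the
    genes with nonzero coefficients at the minimizing alpha; the score cutoff
    is the median training SPGIScore.
    """
    _check_survival(survival)
    if len(genes) < 2:
        raise ValueError("LASSO-Cox needs at least 2 candidate genes")
    survival = survival.loc[log2_expr.columns]
    n_events = int(survival["event"].sum())
    if n_events < n_folds:
        raise ValueError(f"need at least {n_folds} events, have {n_events}")

    x = log2_expr.loc[genes].T  # samples x genes
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        dropped = list(sd.index[sd == 0])
        warnings.warn(f"constant genes dropped before LASSO: {dropped}")
        genes = [g for g in genes if g not in dropped]
        if len(genes) < 2:
            raise ValueError("fewer than 2 non-constant candidate genes")
        x = x[genes]
        mean, sd = mean[genes], sd[genes]
    z = ((x - mean) / sd).to_numpy(dtype=float)
    y = Surv.from_arrays(
        event=survival["event"].to_numpy(bool), time=survival["time"].to_numpy(float)
    )

    path_model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, normalize=False
    )
    path_model.fit(z, y)
    alphas = np.asarray(path_model.alphas_)

    time = survival["time"].to_numpy(float)
    event = survival["event"].to_numpy(int)
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, len(alphas)))
    for f, (train_idx, test_idx) in enumerate(folds.split(z)):
        if event[test_idx].sum() == 0:
            dev[f] = np.nan
            continue
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, normalize=False)
        fold_fit.fit(z[train_idx], y[train_idx])
        coefs = fold_fit.coef_  # genes x alphas (on the common path)
        fold_alphas = np.asarray(fold_fit.alphas_)
        lp_all = z[test_idx] @ coefs
        for a_idx in range(coefs.shape[1]):
            dev[f, a_idx] = -2.0 * breslow_partial_loglik(
                lp_all[:, a_idx], time[test_idx], event[test_idx]
            )
        if len(fold_alphas) < len(alphas):  # path truncated: pad with last value
            dev[f, len(fold_alphas):] = dev[f, len(fold_alphas) - 1]
    mean_dev = np.nanmean(dev, axis=0)
    best = int(np.argmin(mean_dev))
    alpha_star = float(alphas[best])

    coef = pd.Series(path_model.coef_[:, best], index=genes)
    active = coef[coef != 0]
    if active.empty:
        raise ValueError(
            "LASSO kept no genes at the CV-optimal penalty; extend the alpha grid "
            "(smaller alpha_min_ratio) or supply stronger candidates"
        )
    model = SPGIModel(
        genes=tuple(active.index),
        coefficients=active,
        train_mean=mean[active.index],
        train_sd=sd[active.index],
        cutoff=0.0,
        cv_alphas=alphas,
        cv_deviance=mean_dev,
        alpha=alpha_star,
        seed=seed,
    )
    scores = spgi_score(model, log2_expr)["score"]
    object.__setattr__(model, "cutoff", float(scores.median()))
    return model


def spgi_score(model: SPGIModel, log2_expr: pd.DataFrame) -> pd.DataFrame:
    """Per-sample SPGIScore and high/low stratum at the training-median cutoff."""
    missing = [g for g in model.genes if g not in log2_expr.index]
    if missing:
        raise KeyError(f"model gene(s) missing from expression matrix: {missing}")
    x = log2_expr.loc[list(model.genes)].T
    z = (x - model.train_mean) / model.train_sd
    score = z.to_numpy(dtype=float) @ model.coefficients.to_numpy(dtype=float)
    scores = pd.Series(score, index=log2_expr.columns, name="score")
    return pd.DataFrame({"score": scores, "high_risk": scores > model.cutoff})


def evaluate_prognosis(
    scores: pd.Series,
    strata: pd.Series,
    survival: pd.DataFrame,
    horizons_years: tuple[float, ...] = (1.0, 3.0, 5.0),
) -> dict:
    """Log-rank test, Harrell concordance, and IPCW time-dependent AUC.

    ``strata`` is boolean (high risk). AUC uses inverse-probability-of-
    censoring-weighted cumulative/dynamic estimates at the given horizons
    (years, converted at 365.25 d/y); horizons beyond follow-up are reported
    as None.
    """
    _check_survival(survival)
    survival = survival.loc[scores.index]
    strata = strata.reindex(scores.index)
    if strata.sum() == 0 or (~strata.astype(bool)).sum() == 0:
        raise ValueError("both risk strata must be nonempty")
    hi = strata.astype(bool)
    lr = logrank_test(
        survival.loc[hi, "time"],
        survival.loc[~hi, "time"],
        event_observed_A=survival.loc[hi, "event"],
        event_observed_B=survival.loc[~hi, "event"],
    )
    cindex = concordance_index(
        survival["time"], -scores, event_observed=survival["event"]
    )
    y = Surv.from_arrays(
        event=survival["event"].to_numpy(bool), time=survival["time"].to_numpy(float)
    )
    aucs: dict[str, float | None] = {}
    t_obs = survival["time"].to_numpy(float)
    for h in horizons_years:
        t = h * DAYS_PER_YEAR
        if not (t_obs.min() < t < t_obs.max()):
            aucs[f"auc_{h:g}y"] = None
            continue
        try:
            auc, _ = cumulative_dynamic_auc(y, y, scores.to_numpy(float), [t])
            aucs[f"auc_{h:g}y"] = float(auc[0])
        except ValueError:
            aucs[f"auc_{h:g}y"] = None
    return {
        "logrank_p": float(lr.p_value),
        "logrank_statistic": float(lr.test_statistic),
        "concordance": float(cindex),
        "n_high": int(hi.sum()),
        "n_low": int((~hi).sum()),
        **aucs,
    }
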