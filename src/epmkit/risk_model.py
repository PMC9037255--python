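"""Prognostic modelling: univariate Cox screening, LASSO-Cox selection,
risk score, optimal survival cutpoint, KM/log-rank and time-dependent AUC.

The univariate Cox fit is a one-parameter Newton iteration on the Breslow
partial likelihood (Efron weighting available), exposing the Wald p-value and
the score statistic at beta = 0, which for a binary covariate equals the
log-rank statistic on tie-free data.  LASSO-Cox uses the coordinate-descent
penalised path of scikit-survival with the penalty chosen by cross-validated
partial likelihood.  The risk score is the paper-style linear predictor
RiskScore = sum(expression * coefficient); the cutpoint is the maximally
selected log-rank statistic over observed score values (minprop guard).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from ._util import json_dumps_stable
from .data_io import ClinicalTable

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
BETA_CAP = 10.0


# ------------------------------------------------------- partial likelihood

def _breslow_suffstats(x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: float):
    """Log partial likelihood, score and information for a 1-D Cox model
    with Breslow tie handling."""
    order = np.argsort(-time, kind="stable")  # descending time
    xs, ts, es = x[order], time[order], event[order]
    w = np.exp(beta * xs)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * xs)
    s2 = np.cumsum(w * xs**2)
    # risk set of an event at t = all with time >= t: the last index of the
    # tied block in descending order
    last_in_block = np.searchsorted(-ts, -ts, side="right") - 1
    ev = es == 1
    S0 = s0[last_in_block[ev]]
    S1 = s1[last_in_block[ev]]
    S2 = s2[last_in_block[ev]]
    ll = float(np.sum(beta * xs[ev] - np.log(S0)))
    score = float(np.sum(xs[ev] - S1 / S0))
    info = float(np.sum(S2 / S0 - (S1 / S0) ** 2))
    return ll, score, info


def breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of a linear predictor ``lp``."""
    order = np.argsort(-time, kind="stable")
    lps, ts, es = lp[order], time[order], event[order]
    w = np.exp(lps - lps.max())  # stabilised
    s0 = np.cumsum(w)
    last_in_block = np.searchsorted(-ts, -ts, side="right") - 1
    ev = es == 1
    return float(np.sum(lps[ev] - lps.max() - np.log(s0[last_in_block[ev]])))


# ------------------------------------------------------------- univariate

@dataclass
class CoxScreenResult:
    gene: str
    beta: float
    hr: float
    se: float
    p: float
    score_chi2: float
    selected: bool = False


def univariate_cox(
    x: np.ndarray, clinical: ClinicalTable, gene: str = "", p_cut: float = 0.01
) -> CoxScreenResult:
    """One-covariate Cox PH fit (Breslow ties, Newton-Raphson, Wald p).

    A monotone likelihood (perfect separation) is capped at |beta| = 10 with
    a warning.
    """
    x = np.asarray(x, float)
    time, event = clinical.time, clinical.event
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.all(x == x[0]):
        raise ValueError("constant covariate")
    # standardise internally for numerical stability; back-transform beta
    scale = x.std()
    xs = (x - x.mean()) / scale

    _, u0, i0 = _breslow_suffstats(xs, time, event, 0.0)
    score_chi2 = u0**2 / i0 if i0 > 0 else 0.0

    beta = 0.0
    capped = False
    for _ in range(50):
        ll, u, info = _breslow_suffstats(xs, time, event, beta)
        if info <= 1e-12:
            break
        step = u / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(beta) * 1.0 / scale > BETA_CAP:
            beta = np.sign(beta) * BETA_CAP * scale
            capped = True
            break
        if abs(step) < 1e-10:
            break
    if capped:
        log.warning("%s: monotone partial likelihood; beta capped at +/-%g", gene, BETA_CAP)
    _, _, info = _breslow_suffstats(xs, time, event, beta)
    se_std = 1.0 / np.sqrt(info) if info > 0 else np.inf
    beta_orig = beta / scale
    se_orig = se_std / scale
    wald = (beta / se_std) ** 2 if np.isfinite(se_std) else 0.0
    p = float(chi2_dist.sf(wald, df=1))
    return CoxScreenResult(
        gene=gene,
        beta=float(beta_orig),
        hr=float(np.exp(np.clip(beta_orig, -700, 700))),
        se=float(se_orig),
        p=p,
        score_chi2=float(score_chi2),
        selected=p < p_cut,
    )


def cox_screen(
    expr: pd.DataFrame, clinical: ClinicalTable, p_cut: float = 0.01
) -> pd.DataFrame:
    """Univariate Cox per gene (rows of ``expr``); columns beta, HR, p, selected."""
    cols = list(expr.columns)
    if cols != list(clinical.sample_ids):
        clinical = clinical.subset(cols)
    rows = []
    for gene, row in expr.iterrows():
        x = row.to_numpy(float)
        if np.all(x == x[0]):
            continue
        r = univariate_cox(x, clinical, gene=str(gene), p_cut=p_cut)
        rows.append({"gene": r.gene, "beta": r.beta, "HR": r.hr, "p": r.p, "selected": r.selected})
    return pd.DataFrame(rows).set_index("gene")


# ------------------------------------------------------------------ LASSO

@dataclass
class RiskModel:
    genes: list[str]
    coef: np.ndarray
    lambda_: float
    cutpoint: float | None = None
    cv_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self) -> str:
        return json_dumps_stable(
            {
                "genes": self.genes,
                "coef": [float(c) for c in self.coef],
                "lambda": self.lambda_,
                "cutpoint": self.cutpoint,
            }
        )


def lasso_cox_select(
    expr: pd.DataFrame,
    clinical: ClinicalTable,
    n_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "min",
    alphas: np.ndarray | None = None,
) -> RiskModel:
    """L1-penalised Cox gene selection with CV-partial-likelihood lambda choice.

    ``expr`` is genes x samples (already on the scale the risk score will use).
    Features are standardised internally; returned coefficients are on the
    input scale.
    """
    from sklearn.model_selection import KFold
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if expr.shape[0] < 2:
        raise ValueError("need at least 2 candidate genes")
    cols = list(expr.columns)
    if cols != list(clinical.sample_ids):
        clinical = clinical.subset(cols)
    if clinical.event.sum() < 10:
        raise ValueError("need at least 10 events for LASSO-Cox")

    X = expr.to_numpy(float).T  # samples x genes
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant gene rows; remove before LASSO")
    Xs = (X - mu) / sd
    y = Surv.from_arrays(event=clinical.event.astype(bool), time=clinical.time)

    if alphas is None:
        full = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01, n_alphas=60)
    else:
        full = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=np.asarray(alphas, float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(Xs, y)
    alphas = full.alphas_

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_pl = np.zeros((n_folds, len(alphas)))
    for f, (tr, te) in enumerate(kf.split(Xs)):
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(Xs[tr], y[tr])
        coefs = m.coef_  # (n_genes, n_fitted_alphas)
        fitted = list(m.alphas_)
        for a_i, a in enumerate(alphas):
            if a in fitted:
                c = coefs[:, fitted.index(a)]
            else:  # path may stop early; reuse the closest fitted alpha
                c = coefs[:, int(np.argmin(np.abs(np.array(fitted) - a)))]
            lp = Xs[te] @ c
            cv_pl[f, a_i] = breslow_loglik(lp, clinical.time[te], clinical.event[te])
    mean_pl = cv_pl.mean(axis=0)
    se_pl = cv_pl.std(axis=0, ddof=1) / np.sqrt(n_folds)
    if lambda_rule == "min":
        best = int(np.argmax(mean_pl))
    elif lambda_rule == "1se":
        thresh = mean_pl.max() - se_pl[int(np.argmax(mean_pl))]
        ok = np.where(mean_pl >= thresh)[0]
        best = int(ok[np.argmax(alphas[ok])])
    else:
        raise ValueError("lambda_rule must be 'min' or '1se'")
    lam = float(alphas[best])

    coef_std = full.coef_[:, best]
    nonzero = np.flatnonzero(coef_std)
    if nonzero.size == 0:
        raise ValueError(
            "all coefficients are zero at the chosen lambda; try lambda_rule='min' "
            "or a denser alpha grid"
        )
    genes = [expr.index[i] for i in nonzero]
    coef = coef_std[nonzero] / sd[nonzero]  # back to input scale
    cv_table = pd.DataFrame({"lambda": alphas, "cv_logpl": mean_pl, "se": se_pl})
    return RiskModel(genes=[str(g) for g in genes], coef=coef, lambda_=lam, cv_table=cv_table)


def risk_score(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """RiskScore = sum over signature genes of expression x coefficient."""
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"model genes missing from expression matrix: {missing}")
    sub = expr.loc[model.genes].to_numpy(float)
    return pd.Series(sub.T @ model.coef, index=expr.columns, name="risk_score")


# -------------------------------------------------------- log-rank helpers

def logrank_statistic(time, event, group) -> tuple[float, float]:
    """Two-group log-rank: (observed-expected, hypergeometric variance)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group[order]
    n = len(t)
    o_minus_e = 0.0
    var = 0.0
    i = 0
    at_risk = n
    at_risk_1 = int(g.sum())
    while i < n:
        j = i
        d = d1 = 0
        c = c1 = 0
        while j < n and t[j] == t[i]:
            if e[j]:
                d += 1
                d1 += int(g[j])
            else:
                c += 1
                c1 += int(g[j])
            j += 1
        if d > 0 and at_risk > 1:
            frac = at_risk_1 / at_risk
            o_minus_e += d1 - d * frac
            var += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        at_risk -= d + c
        at_risk_1 -= d1 + c1
        i = j
    return o_minus_e, var


@dataclass
class CutpointResult:
    cutpoint: float
    high: np.ndarray  # boolean, score > cutpoint
    statistic: float  # |standardised log-rank| at the cutpoint


def optimal_cutpoint(
    scores: np.ndarray, clinical: ClinicalTable, minprop: float = 0.1
) -> CutpointResult:
    """Maximally selected log-rank cutpoint over observed score values.

    Candidates are observed scores whose split leaves at least ``minprop`` of
    samples in each group; ties in the statistic resolve to the smaller cut.
    """
    scores = np.asarray(scores, float)
    n = len(scores)
    if len(np.unique(scores)) < 2:
        raise ValueError("need at least 2 distinct scores")
    if clinical.event.sum() < 2:
        raise ValueError("need at least 2 events")
    uniq = np.unique(scores)
    best = None
    for cut in uniq[:-1]:  # the largest value leaves an empty high group
        high = scores > cut
        n_high = int(high.sum())
        if n_high < minprop * n or (n - n_high) < minprop * n:
            continue
        ome, var = logrank_statistic(clinical.time, clinical.event, high)
        z = abs(ome) / np.sqrt(var) if var > 0 else 0.0
        if best is None or z > best[0] + 1e-12:
            best = (z, float(cut))
    if best is None:
        raise ValueError("no cutpoint satisfies the minprop constraint")
    z, cut = best
    return CutpointResult(cutpoint=cut, high=scores > cut, statistic=z)


# ------------------------------------------------------------- evaluation

@dataclass
class SurvivalEvaluation:
    logrank_chi2: float
    logrank_p: float
    auc_at: dict[float, float]
    km_curves: dict[str, pd.DataFrame]

    def to_json(self) -> str:
        return json_dumps_stable(
            {
                "logrank_chi2": self.logrank_chi2,
                "logrank_p": self.logrank_p,
                "auc_at_years": {str(k): v for k, v in self.auc_at.items()},
            }
        )


def km_logrank(groups: np.ndarray, clinical: ClinicalTable) -> SurvivalEvaluation:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    groups = np.asarray(groups)
    names = sorted(set(groups.tolist()), key=str)
    if len(names) != 2:
        raise ValueError("exactly two groups are required")
    curves = {}
    for name in names:
        mask = groups == name
        kmf = KaplanMeierFitter()
        kmf.fit(clinical.time[mask], clinical.event[mask], label=str(name))
        sf = kmf.survival_function_
        curves[str(name)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    m0, m1 = groups == names[0], groups == names[1]
    res = logrank_test(
        clinical.time[m0], clinical.time[m1], clinical.event[m0], clinical.event[m1]
    )
    return SurvivalEvaluation(
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        auc_at={},
        km_curves=curves,
    )


def time_dependent_auc(
    scores: np.ndarray,
    clinical: ClinicalTable,
    horizons_years: list[float],
    train_clinical: ClinicalTable | None = None,
) -> dict[float, float]:
    """Cumulative/dynamic AUC at each horizon (years), KM-weighted for censoring.

    Horizons with no cases or no controls report NaN.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    scores = np.asarray(scores, float)
    if train_clinical is None:
        train_clinical = clinical
    y_train = Surv.from_arrays(event=train_clinical.event.astype(bool), time=train_clinical.time)
    y_test = Surv.from_arrays(event=clinical.event.astype(bool), time=clinical.time)
    out: dict[float, float] = {}
    for h in horizons_years:
        t = h * DAYS_PER_YEAR
        cases = np.sum((clinical.time <= t) & (clinical.event == 1))
        controls = np.sum(clinical.time > t)
        if cases == 0 or controls == 0 or t >= clinical.time.max():
            out[h] = float("nan")
            continue
        try:
            auc, _ = cumulative_dynamic_auc(y_train, y_test, scores, [t])
            out[h] = float(auc[0])
        except ValueError as exc:  # e.g. horizon beyond censoring support
            log.warning("AUC at %.3g years undefined: %s", h, exc)
            out[h] = float("nan")
    return out
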