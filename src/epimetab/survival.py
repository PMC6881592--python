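"""Median-split Kaplan-Meier survival screening with log-rank testing and
univariate Cox regression per gene.

Tumor samples are split at the median expression of each gene (ties at the
median go to the low group); the two groups are compared with the log-rank
test, and a univariate Cox proportional-hazards model on the high/low
indicator yields the hazard ratio of high expression with a Wald 95% CI.

The Kaplan-Meier estimator and log-rank test are delegated to lifelines. The
single-covariate Cox fit is a partial-likelihood Newton-Raphson implemented
here, with Breslow tie handling by default (Efron available); lifelines'
CoxPHFitter supports only Efron ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .config import PipelineConfig
from .datatypes import ExpressionMatrix, SampleAnnotation, ValidationError

HIGH, LOW = "high", "low"


def median_split(values: pd.Series) -> pd.Series:
    """Label samples high (> median) / low (<= median) by expression.

    Ties at the median go to the low group. All-identical values cannot be
    split and raise.
    """
    v = pd.Series(values, dtype=float)
    if v.nunique() < 2:
        raise ValidationError("cannot median-split constant values")
    med = v.median()
    labels = pd.Series(np.where(v > med, HIGH, LOW), index=v.index)
    if (labels == HIGH).sum() == 0:
        raise ValidationError("median split produced an empty high group")
    return labels


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate; columns ``time`` and ``survival``.

    S(0) = 1; right censoring respected; the curve is flat beyond the last
    event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValidationError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank_test(times, events, groups):
    """Two-group log-rank test; returns ``(chi2, p)``.

    Standard observed-minus-expected statistic with hypergeometric variance at
    each distinct event time, referred to chi-square with 1 df.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if events.sum() < 1:
        raise ValidationError("log-rank needs at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def _cox_derivatives(beta, times, events, x, ties):
    """Log partial likelihood gradient and Hessian for one covariate."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    t_sorted = times[order]
    e_sorted = events[order]
    x_sorted = x[order]
    theta = np.exp(beta * x_sorted)
    # running sums over the risk set (everyone with time >= t)
    s0 = np.cumsum(theta)
    s1 = np.cumsum(x_sorted * theta)
    s2 = np.cumsum(x_sorted**2 * theta)
    grad, hess = 0.0, 0.0
    i = 0
    n = len(t_sorted)
    while i < n:
        j = i
        while j < n and t_sorted[j] == t_sorted[i]:
            j += 1
        # risk set at this time = indices [0, j)
        ev = e_sorted[i:j].astype(bool)
        d = int(ev.sum())
        if d > 0:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            xe = x_sorted[i:j][ev]
            grad += xe.sum()
            if ties == "breslow":
                grad -= d * S1 / S0
                hess -= d * (S2 / S0 - (S1 / S0)**2)
            else:  # efron
                th_e = theta[i:j][ev]
                S0d, S1d, S2d = th_e.sum(), (xe * th_e).sum(), (xe**2 * th_e).sum()
                for ell in range(d):
                    f = ell / d
                    D0 = S0 - f * S0d
                    D1 = S1 - f * S1d
                    D2 = S2 - f * S2d
                    grad -= D1 / D0
                    hess -= D2 / D0 - (D1 / D0)**2
        i = j
    return grad, hess


def cox_univariate(times, events, covariate, ties: str = "breslow",
                   max_iter: int = 50, tol: float = 1e-9):
    """Single-covariate Cox proportional-hazards fit by Newton-Raphson.

    Returns a dict with ``hr``, ``ci_low``, ``ci_high``, ``p``, ``coef``,
    ``se`` and ``separation``. Breslow tie handling by default. Monotone
    partial likelihood (perfect separation) is flagged, not raised;
    non-convergence raises with diagnostics.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if events.sum() < 1:
        raise ValidationError("Cox fit needs at least one event")
    if np.all(x == x[0]):
        raise ValidationError("Cox covariate is constant")
    if ties not in ("breslow", "efron"):
        raise ValidationError("ties must be 'breslow' or 'efron'")
    # standardize for numerical stability; coefficient rescaled back
    scale = x.std()
    xs = (x - x.mean()) / scale
    beta, separation = 0.0, False
    for _ in range(max_iter):
        grad, hess = _cox_derivatives(beta, times, events, xs, ties)
        if hess == 0:
            raise ValidationError("Cox fit: singular information")
        step = grad / hess
        beta -= step
        if abs(beta) > 50:
            separation = True
            break
        if abs(step) < tol:
            break
    else:
        raise ValidationError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(beta={beta:.3g}, grad={grad:.3g})")
    grad, hess = _cox_derivatives(beta, times, events, xs, ties)
    se_s = float(np.sqrt(-1.0 / hess)) if hess < 0 else float("inf")
    coef, se = beta / scale, se_s / scale
    z = coef / se if se > 0 else np.inf
    zcrit = stats.norm.ppf(0.975)
    return {"hr": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - zcrit * se)),
            "ci_high": float(np.exp(coef + zcrit * se)),
            "p": float(2 * stats.norm.sf(abs(z))),
            "coef": float(coef), "se": float(se),
            "separation": separation}


@dataclass
class SurvivalResults:
    """Per-gene survival screen results.

    ``table`` columns: gene, n_high, n_low, logrank_chi2, logrank_p, hr,
    hr_ci_low, hr_ci_high, cox_p, significant. ``skipped`` maps genes that
    could not be evaluated to the reason.
    """

    table: pd.DataFrame
    skipped: dict
    config: PipelineConfig

    @property
    def significant_genes(self) -> list[str]:
        return sorted(self.table.loc[self.table["significant"], "gene"])

    def summary(self) -> str:
        return (f"Survival screen (median split, log-rank P < "
                f"{self.config.survival_p})\n"
                f"  genes evaluated: {len(self.table)}, "
                f"significant: {len(self.significant_genes)}, "
                f"skipped: {len(self.skipped)}")


class SurvivalScreen:
    """Median-split KM / log-rank / univariate Cox screen over a gene list.

    Only tumor samples with both survival time and event flag are used; the
    hazard ratio is reported for the high-expression group vs low.
    """

    def __init__(self, expr: ExpressionMatrix, annotation: SampleAnnotation,
                 genes=None, config: PipelineConfig = None):
        self.config = config or PipelineConfig()
        self.expr = expr
        self.annotation = annotation
        self.genes = list(genes) if genes is not None else expr.gene_ids

    def fit(self) -> SurvivalResults:
        cfg = self.config
        ann = self.annotation.table
        has_surv = "survival_months" in ann.columns
        evaluable = [s for s in self.expr.sample_ids
                     if s in ann.index
                     and ann.at[s, "group"] == "tumor"
                     and has_surv
                     and pd.notna(ann.at[s, "survival_months"])
                     and pd.notna(ann.at[s, "event"])]
        if len(evaluable) < 4:
            raise ValidationError("survival screen needs >= 4 evaluable samples")
        rows, skipped = [], {}
        times = ann.loc[evaluable, "survival_months"].to_numpy(float)
        events = ann.loc[evaluable, "event"].to_numpy(int)
        for gene in self.genes:
            if gene not in self.expr.values.index:
                skipped[gene] = "gene absent from expression matrix"
                continue
            values = self.expr.values.loc[gene, evaluable]
            try:
                labels = median_split(values)
                chi2, lr_p = logrank_test(times, events, labels.to_numpy())
                cox = cox_univariate(times, events,
                                     (labels == HIGH).astype(float),
                                     ties=cfg.cox_ties)
            except ValidationError as exc:
                skipped[gene] = str(exc)
                continue
            rows.append({"gene": gene,
                         "n_high": int((labels == HIGH).sum()),
                         "n_low": int((labels == LOW).sum()),
                         "logrank_chi2": chi2, "logrank_p": lr_p,
                         "hr": cox["hr"], "hr_ci_low": cox["ci_low"],
                         "hr_ci_high": cox["ci_high"], "cox_p": cox["p"],
                         "significant": lr_p < cfg.survival_p})
        columns = ["gene", "n_high", "n_low", "logrank_chi2", "logrank_p",
                   "hr", "hr_ci_low", "hr_ci_high", "cox_p", "significant"]
        return SurvivalResults(table=pd.DataFrame(rows, columns=columns),
                               skipped=skipped, config=cfg)
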