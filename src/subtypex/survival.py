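"""Kaplan-Meier curves, log-rank tests, and Cox proportional hazards models.

The Cox model is fitted by Newton iteration on the partial likelihood
with Breslow (default) or Efron handling of tied event times; Wald
confidence intervals and p-values per covariate.  ``evaluate_triples``
runs the full prognostic assessment of exclusive triples: carrier versus
all-wild-type log-rank plus univariate and covariate-adjusted Cox fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlterationMatrix
from .functions import wildtype_samples
from .subtypes import SubtypeCatalog

log = logging.getLogger("subtypex.survival")

__all__ = [
    "km_curve",
    "km_logrank",
    "CoxFit",
    "cox_fit",
    "cox_score_test",
    "evaluate_triples",
]


def km_curve(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier survival estimate with right censoring.

    Returns a table of event times with n_at_risk, n_events and the
    survival probability just after each time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    n = len(times)
    rows = []
    surv = 1.0
    for t in uniq:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        surv *= 1.0 - d / at_risk
        rows.append((t, at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def km_logrank(
    times: np.ndarray, events: np.ndarray, group_labels: np.ndarray
) -> dict:
    """Two-group log-rank test with hypergeometric variance.

    Returns chi_sq, p (1 df), and the KM curve of each group.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(group_labels)
    uniq_groups = np.unique(groups)
    if uniq_groups.size != 2:
        raise ValueError(f"exactly two groups required, got {uniq_groups.size}")
    if (events == 1).sum() < 1:
        raise ValueError("at least one event is required")
    for g in uniq_groups:
        if (groups == g).sum() == 0:
            raise ValueError(f"group {g} has zero subjects")

    g1 = groups == uniq_groups[0]
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_t = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d_t = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        if n_t < 2:
            continue
        e1 = d_t * n1 / n_t
        v = d_t * (n1 / n_t) * (1 - n1 / n_t) * (n_t - d_t) / (n_t - 1)
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        chi_sq = 0.0
    else:
        chi_sq = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi_sq, df=1)) if var > 0 else 1.0
    curves = {
        str(g): km_curve(times[groups == g], events[groups == g]) for g in uniq_groups
    }
    return {"chi_sq": float(chi_sq), "p": p, "o_minus_e": float(o_minus_e), "var": float(var), "km_curves": curves}


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            },
            index=self.names,
        )


def _cox_loglik_grad_hess(
    beta: np.ndarray,
    x: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    n, k = x.shape
    eta = x @ beta
    eta -= eta.max()  # stabilize exponentials; partial likelihood is shift-invariant
    w = np.exp(eta)
    order = np.argsort(-times, kind="stable")  # descending time for cumulative sums
    xs, ws, ts, es = x[order], w[order], times[order], events[order]

    ll = 0.0
    grad = np.zeros(k)
    hess = np.zeros((k, k))
    s0 = 0.0
    s1 = np.zeros(k)
    s2 = np.zeros((k, k))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            s0 += ws[j]
            s1 += ws[j] * xs[j]
            s2 += ws[j] * np.outer(xs[j], xs[j])
            j += 1
        evt = [m for m in range(i, j) if es[m] == 1]
        d = len(evt)
        if d:
            x_evt = xs[evt]
            w_evt = ws[evt]
            sum_eta_evt = np.log(w_evt).sum()
            if ties == "breslow" or d == 1:
                ll += sum_eta_evt - d * np.log(s0)
                mean1 = s1 / s0
                grad += x_evt.sum(axis=0) - d * mean1
                hess -= d * (s2 / s0 - np.outer(mean1, mean1))
            elif ties == "efron":
                w_d = w_evt.sum()
                s1_d = (w_evt[:, None] * x_evt).sum(axis=0)
                s2_d = (w_evt[:, None, None] * np.einsum("ij,ik->ijk", x_evt, x_evt)).sum(axis=0)
                ll += sum_eta_evt
                grad += x_evt.sum(axis=0)
                for r in range(d):
                    f = r / d
                    denom = s0 - f * w_d
                    num1 = s1 - f * s1_d
                    num2 = s2 - f * s2_d
                    ll -= np.log(denom)
                    grad -= num1 / denom
                    hess -= num2 / denom - np.outer(num1, num1) / denom**2
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return ll, grad, hess


def cox_fit(
    design: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox proportional hazards fit by Newton iteration on the partial likelihood.

    Non-convergence and monotone-likelihood separation are reported in
    ``flags`` rather than returned as silent numbers.
    """
    x = design.to_numpy(dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, k = x.shape
    if events.sum() < k:
        raise ValueError("fewer events than covariates")
    if np.any(x.std(axis=0) == 0):
        const = [design.columns[i] for i in range(k) if x[:, i].std() == 0]
        raise ValueError(f"constant covariate(s): {const}")

    beta = np.zeros(k)
    flags: list[str] = []
    converged = False
    ll = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_grad_hess(beta, x, times, events, ties)
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            flags.append("singular_hessian")
            break
        # dampen overly aggressive steps
        if np.abs(step).max() > 5.0:
            step *= 5.0 / np.abs(step).max()
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
    if not converged and "singular_hessian" not in flags:
        flags.append("no_convergence")
    if np.abs(beta).max() > 15.0:
        flags.append("possible_separation")

    ll, grad, hess = _cox_loglik_grad_hess(beta, x, times, events, ties)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        flags.append("singular_hessian")
    zcrit = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
        ci_lo = np.exp(beta - zcrit * se)  # inf CI on separated covariates
        ci_hi = np.exp(beta + zcrit * se)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(
        names=list(design.columns),
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p=p,
        log_likelihood=float(ll),
        n=n,
        n_events=int(events.sum()),
        converged=converged,
        flags=flags,
    )


def cox_score_test(
    design: pd.DataFrame, times: np.ndarray, events: np.ndarray, ties: str = "breslow"
) -> float:
    """Score test statistic at beta = 0 (equals the log-rank chi-square for a
    single binary covariate without ties)."""
    x = design.to_numpy(dtype=float)
    beta = np.zeros(x.shape[1])
    _, grad, hess = _cox_loglik_grad_hess(
        beta, x, np.asarray(times, float), np.asarray(events, int), ties
    )
    return float(grad @ np.linalg.solve(-hess, grad))


_STAGE_BASELINES = {"ajcc_stage": "I", "t_stage": "T1", "n_stage": "N0"}


def _clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Age, gender, and stage dummies against baseline levels I / T1 / N0."""
    cols = {}
    if "age" in clinical:
        cols["age"] = clinical["age"].astype(float)
    if "gender" in clinical:
        cols["gender_male"] = (clinical["gender"].astype(str).str.lower() == "male").astype(float)
    for var, base in _STAGE_BASELINES.items():
        if var not in clinical:
            continue
        levels = sorted(set(clinical[var].dropna().astype(str)) - {base})
        for lev in levels:
            cols[f"{var}_{lev}"] = (clinical[var].astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=clinical.index)


def triple_groups(
    triple_events: tuple[str, str, str],
    matrix: AlterationMatrix,
    catalog: SubtypeCatalog,
    include_pruned: bool = False,
) -> tuple[list[str], list[str]]:
    """Carrier and comparator sample sets for one exclusive triple.

    Carriers are the union of the three subtype member sets; comparators
    are wild-type for all three genes.  Samples mutated in a triple gene
    but pruned from its subtype belong to neither group unless
    ``include_pruned``.
    """
    genes = [matrix.gene_of(ev) for ev in triple_events]
    carriers: set[str] = set()
    for ev in triple_events:
        carriers |= set(matrix.carriers(ev))
    if include_pruned:
        for g in genes:
            carriers |= set(matrix.carriers(g))
    comparator = set(wildtype_samples(matrix, genes)) - carriers
    return sorted(carriers), sorted(comparator)


def evaluate_triples(
    triples: list,
    matrix: AlterationMatrix,
    catalog: SubtypeCatalog,
    clinical: pd.DataFrame,
    endpoint: str = "os",
    ties: str = "breslow",
    include_pruned: bool = False,
) -> pd.DataFrame:
    """Log-rank plus univariate and multivariate Cox per exclusive triple.

    The multivariate model adds age, gender, and AJCC/T/N stage dummies;
    ``independent_predictor`` flags multivariate carrier p < 0.05.
    Complete-case analysis per model with n reported.
    """
    if endpoint not in ("os", "dss"):
        raise ValueError("endpoint must be 'os' or 'dss'")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in clinical or ecol not in clinical:
        raise ValueError(f"clinical table lacks {tcol}/{ecol}")

    rows = []
    for tr in triples:
        events3 = tuple(tr.events) if hasattr(tr, "events") else tuple(tr)
        name = "|".join(events3)
        carriers, comparator = triple_groups(events3, matrix, catalog, include_pruned)
        if not comparator:
            raise ValueError(f"comparator group empty for triple {name}")
        if not carriers:
            raise ValueError(f"carrier group empty for triple {name}")
        used = [s for s in carriers + comparator if s in clinical.index]
        sub = clinical.loc[used]
        base_ok = sub[tcol].notna() & sub[ecol].notna()
        sub = sub.loc[base_ok]
        if int(sub[ecol].sum()) == 0:
            raise ValueError(f"endpoint {endpoint} has no events for triple {name}")
        indicator = pd.Series(
            [1.0 if s in set(carriers) else 0.0 for s in sub.index], index=sub.index, name="carrier"
        )

        lr = km_logrank(sub[tcol].to_numpy(), sub[ecol].to_numpy().astype(int), indicator.to_numpy())

        uni = cox_fit(indicator.to_frame(), sub[tcol].to_numpy(), sub[ecol].to_numpy(), ties=ties)

        design = _clinical_design(sub)
        design.insert(0, "carrier", indicator)
        keep_rows = design.notna().all(axis=1)
        design_cc = design.loc[keep_rows]
        dropped_cols = [c for c in design_cc.columns if design_cc[c].std() == 0]
        for c in dropped_cols:
            log.warning("evaluate_triples: covariate %s constant in complete cases; dropped", c)
        design_cc = design_cc.drop(columns=dropped_cols)
        multi = cox_fit(
            design_cc,
            sub.loc[keep_rows, tcol].to_numpy(),
            sub.loc[keep_rows, ecol].to_numpy(),
            ties=ties,
        )
        ci = multi.summary().loc["carrier"]
        ui = uni.summary().loc["carrier"]
        rows.append(
            {
                "triple": name,
                "n_carriers": len(carriers),
                "n_comparator": len(comparator),
                "logrank_chi_sq": lr["chi_sq"],
                "logrank_p": lr["p"],
                "uni_hr": ui["hr"],
                "uni_ci_lower": ui["ci_lower"],
                "uni_ci_upper": ui["ci_upper"],
                "uni_p": ui["p"],
                "multi_hr": ci["hr"],
                "multi_ci_lower": ci["ci_lower"],
                "multi_ci_upper": ci["ci_upper"],
                "multi_p": ci["p"],
                "multi_n": multi.n,
                "independent_predictor": bool(ci["p"] < 0.05),
                "flags": ";".join(sorted(set(uni.flags + multi.flags))),
            }
        )
    return pd.DataFrame(rows)
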