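"""Margin-constrained mutual-exclusivity and co-occurrence testing.

The background model assigns each event/sample cell an alteration
probability ``p_ij = logistic(mu_i + lam_j)`` fitted so that expected row
and column sums match the observed margins (maximum-entropy under margin
constraints).  Pair overlaps are then tested against an exact
Poisson-binomial null.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AlterationMatrix

log = logging.getLogger("subtypex.exclusivity")

__all__ = [
    "BackgroundModel",
    "ExclusivityResult",
    "TripleResult",
    "fit_background",
    "extend_background_to_subtypes",
    "poisson_binomial_pmf",
    "poisson_binomial_cdf",
    "test_pair",
    "bh_fdr",
    "screen_pairs",
    "find_triples",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class BackgroundModel:
    event_ids: list[str]
    sample_ids: list[str]
    p: np.ndarray  # events x samples, fitted probabilities
    mu: np.ndarray  # per-event effect (nan for degenerate rows)
    lam: np.ndarray  # per-sample effect (nan for degenerate columns)
    max_margin_residual: float

    def prob(self, event_id: str) -> np.ndarray:
        return self.p[self.event_ids.index(event_id)]


def _fit_margins(
    values: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Alternating per-coordinate Newton updates on mu (rows) and lam (cols).

    Degenerate all-0 / all-1 rows and columns are clamped to 0/1 and
    excluded from the fit.
    """
    n_ev, n_s = values.shape
    mu = np.full(n_ev, np.nan)
    lam = np.full(n_s, np.nan)
    p = values.astype(float).copy()  # degenerate cells keep their observed value

    # peel degenerate rows/columns until the live block has interior margins;
    # a row all-0 (or all-1) within live columns is clamped, which can in turn
    # degenerate further columns
    row_live = np.ones(n_ev, dtype=bool)
    col_live = np.ones(n_s, dtype=bool)
    while True:
        sub = values[np.ix_(row_live, col_live)]
        if sub.size == 0:
            return p, mu, lam, 0.0
        rs, cs = sub.sum(axis=1), sub.sum(axis=0)
        bad_rows = (rs == 0) | (rs == sub.shape[1])
        bad_cols = (cs == 0) | (cs == sub.shape[0])
        if not bad_rows.any() and not bad_cols.any():
            break
        row_live[np.where(row_live)[0][bad_rows]] = False
        col_live[np.where(col_live)[0][bad_cols]] = False

    r_idx = np.where(row_live)[0]
    c_idx = np.where(col_live)[0]
    sub = values[np.ix_(r_idx, c_idx)].astype(float)
    r_target = sub.sum(axis=1)
    c_target = sub.sum(axis=0)
    m, s = sub.shape
    mu_l = np.log((r_target + 0.5) / (s - r_target + 0.5))
    lam_l = np.zeros(s)

    resid = np.inf
    for _ in range(max_iter):
        z = mu_l[:, None] + lam_l[None, :]
        q = _sigmoid(z)
        # Newton step on each mu_i holding lam fixed (1-D monotone problems)
        g = q.sum(axis=1) - r_target
        h = (q * (1 - q)).sum(axis=1)
        mu_l -= np.where(h > 1e-12, g / np.maximum(h, 1e-12), 0.0)
        z = mu_l[:, None] + lam_l[None, :]
        q = _sigmoid(z)
        g = q.sum(axis=0) - c_target
        h = (q * (1 - q)).sum(axis=0)
        lam_l -= np.where(h > 1e-12, g / np.maximum(h, 1e-12), 0.0)
        q = _sigmoid(mu_l[:, None] + lam_l[None, :])
        resid = max(
            np.abs(q.sum(axis=1) - r_target).max(initial=0.0),
            np.abs(q.sum(axis=0) - c_target).max(initial=0.0),
        )
        if resid <= tol:
            break
    else:
        raise RuntimeError(
            f"background model did not converge: max margin residual {resid:.3e} > {tol:.1e}"
        )

    # anchor the additive gauge: mean lam = 0
    shift = lam_l.mean()
    lam_l -= shift
    mu_l += shift
    p[np.ix_(r_idx, c_idx)] = _sigmoid(mu_l[:, None] + lam_l[None, :])
    mu[r_idx] = mu_l
    lam[c_idx] = lam_l
    return p, mu, lam, float(resid)


def fit_background(
    matrix: AlterationMatrix, tol: float = 1e-6, max_iter: int = 10_000
) -> BackgroundModel:
    """Fit per-cell alteration probabilities matching observed row/column margins."""
    values = matrix.values.to_numpy().astype(float)
    p, mu, lam, resid = _fit_margins(values, tol, max_iter)
    return BackgroundModel(
        event_ids=matrix.event_ids,
        sample_ids=matrix.sample_ids,
        p=p,
        mu=mu,
        lam=lam,
        max_margin_residual=resid,
    )


def extend_background_to_subtypes(
    model: BackgroundModel,
    matrix: AlterationMatrix,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> BackgroundModel:
    """Background rates for subtype rows with per-sample effects frozen.

    Sample effects ``lam`` reflect mutation load and are fitted once on the
    gene-level matrix; each subtype row then gets its own ``mu`` so that the
    expected row sum matches the subtype carrier count.
    """
    sub_events = matrix.subtype_events()
    if not sub_events:
        return model
    if matrix.sample_ids != model.sample_ids:
        raise ValueError("subtype matrix sample order differs from the fitted model")
    lam = model.lam
    live = ~np.isnan(lam)
    lam_live = lam[live]

    event_ids = list(model.event_ids)
    p_rows = [model.p]
    mu_ext = [model.mu]
    worst = model.max_margin_residual
    for ev in sub_events:
        row = matrix.values.loc[ev].to_numpy().astype(float)
        target = row.sum()
        p_new = np.zeros(len(model.sample_ids))
        m_val = np.nan
        if target == 0:
            pass
        elif target == live.sum():
            p_new[live] = 1.0
        else:
            m = np.log((target + 0.5) / (live.sum() - target + 0.5))
            for _ in range(max_iter):
                q = _sigmoid(m + lam_live)
                g = q.sum() - target
                if abs(g) <= tol:
                    break
                h = (q * (1 - q)).sum()
                m -= g / max(h, 1e-12)
            q = _sigmoid(m + lam_live)
            worst = max(worst, abs(q.sum() - target))
            p_new[live] = q
            m_val = m
        event_ids.append(ev)
        p_rows.append(p_new[None, :])
        mu_ext.append(np.array([m_val]))

    p_all = np.vstack(p_rows)
    return BackgroundModel(
        event_ids=event_ids,
        sample_ids=model.sample_ids,
        p=p_all,
        mu=np.concatenate(mu_ext),
        lam=lam,
        max_margin_residual=float(worst),
    )


def poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(probs) by DP convolution."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and ((probs < 0).any() or (probs > 1).any()):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.zeros(probs.size + 1)
    pmf[0] = 1.0
    top = 0
    for p in probs:
        if p == 0.0:
            continue
        top += 1
        pmf[1 : top + 1] = pmf[1 : top + 1] * (1 - p) + pmf[:top] * p
        pmf[0] *= 1 - p
    return pmf


def poisson_binomial_cdf(probs: np.ndarray, x: int) -> float:
    """P(X <= x) for X ~ PoissonBinomial(probs).

    The DP convolution is truncated at x + 1 terms: probability mass that
    moves past x never returns, so the truncation is exact for the CDF.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and ((probs < 0).any() or (probs > 1).any()):
        raise ValueError("probabilities must lie in [0, 1]")
    if x < 0:
        return 0.0
    if x >= probs.size:
        return 1.0
    x = int(x)
    pmf = np.zeros(x + 1)
    pmf[0] = 1.0
    top = 0
    for p in probs:
        if p == 0.0:
            continue
        if top < x:
            top += 1
        pmf[1 : top + 1] = pmf[1 : top + 1] * (1 - p) + pmf[:top] * p
        pmf[0] *= 1 - p
    return float(min(1.0, pmf.sum()))


@dataclass
class ExclusivityResult:
    event_a: str
    event_b: str
    overlap: int
    expected_overlap: float
    direction: str  # "mutual_exclusivity" | "co_occurrence"
    p_value: float
    q_value: float | None = None


@dataclass
class TripleResult:
    events: tuple[str, str, str]
    genes: tuple[str, str, str]
    pair_q_values: tuple[float, float, float]


def test_pair(
    model: BackgroundModel,
    matrix: AlterationMatrix,
    event_a: str,
    event_b: str,
    direction: str = "mutual_exclusivity",
) -> ExclusivityResult:
    """Test one event pair against the Poisson-binomial overlap null.

    ME p-value is the lower tail P(X <= overlap); CO is the upper tail
    P(X >= overlap).  Subtype events of the same gene are structurally
    exclusive and refused.
    """
    if direction not in ("mutual_exclusivity", "co_occurrence"):
        raise ValueError(f"unknown direction {direction!r}")
    ga, gb = matrix.gene_of(event_a), matrix.gene_of(event_b)
    if ga == gb and (matrix.is_subtype_event(event_a) or matrix.is_subtype_event(event_b)):
        raise ValueError(
            f"events {event_a} and {event_b} share gene {ga}: structurally exclusive"
        )
    a = matrix.values.loc[event_a].to_numpy().astype(bool)
    b = matrix.values.loc[event_b].to_numpy().astype(bool)
    overlap = int((a & b).sum())
    probs = model.prob(event_a) * model.prob(event_b)
    if direction == "mutual_exclusivity":
        p = poisson_binomial_cdf(probs, overlap)
    else:
        p = 1.0 - poisson_binomial_cdf(probs, overlap - 1)
    return ExclusivityResult(
        event_a=event_a,
        event_b=event_b,
        overlap=overlap,
        expected_overlap=float(probs.sum()),
        direction=direction,
        p_value=float(max(min(p, 1.0), 0.0)),
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def screen_pairs(
    matrix: AlterationMatrix,
    model: BackgroundModel,
    level: str = "gene",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test all admissible unordered pairs for ME and CO at one event level.

    BH correction is applied within each direction family separately.
    Returns a table with columns event_a, event_b, overlap, expected,
    direction, p, q, significant; pairs in lexicographic event order.
    """
    if level == "gene":
        events = sorted(matrix.gene_events())
    elif level == "subtype":
        events = sorted(matrix.subtype_events())
    else:
        raise ValueError(f"unknown level {level!r}")

    pairs = [
        (a, b)
        for a, b in itertools.combinations(events, 2)
        if matrix.gene_of(a) != matrix.gene_of(b)
    ]
    rows: list[dict] = []
    for direction in ("mutual_exclusivity", "co_occurrence"):
        results = [test_pair(model, matrix, a, b, direction) for a, b in pairs]
        qs = bh_fdr(np.array([r.p_value for r in results]))
        for r, q in zip(results, qs):
            rows.append(
                {
                    "event_a": r.event_a,
                    "event_b": r.event_b,
                    "overlap": r.overlap,
                    "expected": r.expected_overlap,
                    "direction": direction,
                    "p": r.p_value,
                    "q": q,
                    "significant": q < q_threshold,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["event_a", "event_b", "overlap", "expected", "direction", "p", "q", "significant"],
    )
    return df


def find_triples(
    table: pd.DataFrame,
    matrix: AlterationMatrix,
    q_threshold: float = 0.05,
) -> list[TripleResult]:
    """Triangles of significant ME pairs spanning three distinct genes."""
    me = table[(table["direction"] == "mutual_exclusivity") & (table["q"] < q_threshold)]
    edge_q: dict[frozenset[str], float] = {}
    adj: dict[str, set[str]] = {}
    for _, row in me.iterrows():
        a, b = row["event_a"], row["event_b"]
        edge_q[frozenset((a, b))] = float(row["q"])
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    triples: list[TripleResult] = []
    nodes = sorted(adj)
    for a in nodes:
        for b in sorted(adj[a]):
            if b <= a:
                continue
            for c in sorted(adj[a] & adj[b]):
                if c <= b:
                    continue
                genes = (matrix.gene_of(a), matrix.gene_of(b), matrix.gene_of(c))
                if len(set(genes)) != 3:
                    continue
                triples.append(
                    TripleResult(
                        events=(a, b, c),
                        genes=genes,
                        pair_q_values=(
                            edge_q[frozenset((a, b))],
                            edge_q[frozenset((a, c))],
                            edge_q[frozenset((b, c))],
                        ),
                    )
                )
    return triples
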