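"""Differential expression, gene-set enrichment, and function assignment.

Subtype-vs-wild-type differential expression uses a negative binomial
Wald test with median-of-ratios size factors and method-of-moments
dispersion.  Enrichment is a one-sided hypergeometric test over a GMT
collection; functions of ME pairs and triples come from intersecting the
members' significant term sets.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import AlterationMatrix, ExpressionMatrix
from .exclusivity import bh_fdr

log = logging.getLogger("subtypex.functions")

__all__ = [
    "filter_expressed",
    "size_factors",
    "de_test",
    "enrich",
    "pair_functions",
    "triple_functions",
    "wildtype_samples",
]


def filter_expressed(
    expr: ExpressionMatrix, min_count: int = 1, min_frac: float = 0.30
) -> ExpressionMatrix:
    """Keep genes with count > ``min_count`` in at least ``min_frac`` of samples."""
    counts = expr.values.to_numpy()
    frac = (counts > min_count).mean(axis=1)
    keep = frac >= min_frac
    return ExpressionMatrix(values=expr.values.loc[keep].copy(), scale=expr.scale)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (geometric-mean reference).

    Genes with a zero count in any sample drop out of the reference, the
    usual convention for count normalization.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has all-positive counts; cannot form reference")
    log_ref = np.log(counts[positive]).mean(axis=1)
    ratios = np.log(counts[positive]) - log_ref[:, None]
    return np.exp(np.median(ratios, axis=0))


def wildtype_samples(matrix: AlterationMatrix, genes: Sequence[str]) -> list[str]:
    """Samples with zero non-silent mutation in every listed gene.

    Shared by the DE and survival stages so 'wild type' means the same
    thing everywhere.
    """
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing}")
    sub = matrix.values.loc[list(genes)].to_numpy()
    mask = sub.sum(axis=0) == 0
    return [s for s, m in zip(matrix.sample_ids, mask) if m]


def de_test(
    expr: ExpressionMatrix,
    subtype_samples: Sequence[str],
    wildtype_samples: Sequence[str],
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Negative binomial Wald test of subtype vs wild-type expression.

    Per gene: normalize by size factors, estimate a method-of-moments
    dispersion from pooled within-group variances (floored at 1e-8), and
    test the log2 fold change with a Wald z statistic.  Returns a table
    with log2_fc, p, q, group means, dispersion, and a ``deg`` flag at
    |log2_fc| >= ``lfc_threshold`` and q < ``q_threshold``.
    """
    a = list(subtype_samples)
    b = list(wildtype_samples)
    if set(a) & set(b):
        raise ValueError("subtype and wild-type groups overlap")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    counts = expr.values[a + b].to_numpy(dtype=float)
    sf = size_factors(counts)
    norm = counts / sf[None, :]
    na, nb = len(a), len(b)
    xa, xb = norm[:, :na], norm[:, na:]

    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)

    # method-of-moments NB dispersion pooled over the two groups:
    # Var(X) = mu + alpha * mu^2  =>  alpha = (s2 - mu) / mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (var_a - mean_a) / np.square(mean_a)
        alpha_b = (var_b - mean_b) / np.square(mean_b)
    alpha = np.nanmax(
        np.vstack([np.full_like(mean_a, 1e-8), (alpha_a * (na - 1) + alpha_b * (nb - 1)) / (na + nb - 2)]),
        axis=0,
    )
    alpha = np.where(np.isfinite(alpha), alpha, 1e-8)

    eps = 1e-8
    log2_fc = np.log2(np.maximum(mean_a, eps)) - np.log2(np.maximum(mean_b, eps))
    # a gene with one constant count everywhere carries no signal: force lfc 0
    constant = (counts == counts[:, :1]).all(axis=1)
    log2_fc = np.where(constant, 0.0, log2_fc)

    # delta-method variance of log(mean) under NB sampling
    se_log_a = np.sqrt((mean_a + alpha * mean_a**2) / na) / np.maximum(mean_a, eps)
    se_log_b = np.sqrt((mean_b + alpha * mean_b**2) / nb) / np.maximum(mean_b, eps)
    se_lfc = np.sqrt(se_log_a**2 + se_log_b**2) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_lfc > 0, log2_fc / np.maximum(se_lfc, 1e-12), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)

    df = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "dispersion": alpha,
        },
        index=expr.values.index,
    )
    df["deg"] = (df["log2_fc"].abs() >= lfc_threshold) & (df["q"] < q_threshold)
    return df


def enrich(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    min_term_size: int = 5,
    max_term_size: int = 2000,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``query_genes`` over a GMT.

    Term gene lists are intersected with the universe first; terms outside
    the configured size bounds are skipped.  BH correction across tested
    terms; ``significant`` marks q < ``q_threshold``.
    """
    uni = set(universe)
    query = set(query_genes)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    if not query:
        return pd.DataFrame(columns=["term", "term_size", "query_size", "overlap", "p", "q", "significant"]).set_index("term")
    m_total = len(uni)
    n_query = len(query)
    rows = []
    for term, genes in gene_sets.items():
        members = set(genes) & uni
        if not (min_term_size <= len(members) <= max_term_size):
            continue
        overlap = len(members & query)
        # upper tail: P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, m_total, len(members), n_query))
        rows.append((term, len(members), n_query, overlap, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=["term", "term_size", "query_size", "overlap", "p", "q", "significant"]).set_index("term")
    df = pd.DataFrame(rows, columns=["term", "term_size", "query_size", "overlap", "p"]).set_index("term")
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["q"] < q_threshold
    return df


def pair_functions(
    pair: tuple[str, str], enrichment_tables: Mapping[str, pd.DataFrame]
) -> set[str]:
    """Significant terms shared by both members of an ME pair."""
    sets = []
    for ev in pair:
        if ev not in enrichment_tables:
            raise KeyError(f"no enrichment table for event {ev}")
        tab = enrichment_tables[ev]
        sets.append(set(tab.index[tab["significant"]]) if len(tab) else set())
    return sets[0] & sets[1]


def triple_functions(pair_function_sets: Sequence[set[str]]) -> set[str]:
    """Terms present in at least two of a triple's three pair sets."""
    if len(pair_function_sets) != 3:
        raise ValueError("a triple has exactly three pair function sets")
    counts: dict[str, int] = {}
    for s in pair_function_sets:
        for term in s:
            counts[term] = counts.get(term, 0) + 1
    return {t for t, c in counts.items() if c >= 2}
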