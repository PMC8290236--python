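"""Transcriptomic subtype discovery within each driver gene's carrier set.

Three-step procedure per driver gene: select the most variable genes by
median absolute deviation, consensus-cluster the carriers with PAM on
Pearson distance under 80% resampling, then prune unstable members by
silhouette width.  Genes with few carriers skip resampling and are split
directly into two PAM clusters.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import AlterationMatrix, ExpressionMatrix, subtype_event_id

log = logging.getLogger("subtypex.subtypes")

__all__ = [
    "ConsensusResult",
    "SubtypeEntry",
    "SubtypeCatalog",
    "gene_mad_profile",
    "compare_heterogeneity",
    "select_top_variable",
    "pearson_distance",
    "pearson_distance_matrix",
    "pam",
    "consensus_cluster",
    "silhouette_widths",
    "silhouette_prune",
    "subtype_all",
]


# ---------------------------------------------------------------------------
# variability profiling


def gene_mad_profile(expr: ExpressionMatrix, sample_set: list[str] | None = None) -> pd.Series:
    """Unscaled median absolute deviation per gene over ``sample_set``."""
    samples = list(sample_set) if sample_set is not None else expr.sample_ids
    if len(samples) == 0:
        raise ValueError("sample set is empty")
    vals = expr.values[samples].to_numpy(dtype=float)
    med = np.median(vals, axis=1, keepdims=True)
    mad = np.median(np.abs(vals - med), axis=1)
    return pd.Series(mad, index=expr.gene_ids, name="mad")


def compare_heterogeneity(mad_a: pd.Series, mad_b: pd.Series) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two MAD profiles.

    Direction is reported as median(a) - median(b).
    """
    if not mad_a.index.equals(mad_b.index):
        raise ValueError("profiles must share the same gene universe")
    a = mad_a.to_numpy(dtype=float)
    b = mad_b.to_numpy(dtype=float)
    if np.all(a == b[0]) and np.all(b == b[0]):
        log.warning("compare_heterogeneity: all values tied; p set to 1")
        return {"statistic": 0.0, "p": 1.0, "median_difference": 0.0}
    res = stats.ranksums(a, b)
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median_difference": float(np.median(a) - np.median(b)),
    }


def select_top_variable(
    expr: ExpressionMatrix, sample_set: list[str] | None = None, n_top: int = 2000
) -> ExpressionMatrix:
    """Top-``n_top`` genes by MAD, log2(x+1)-transformed and median-centered.

    Ties at the cutoff break by gene-id lexicographic order so the
    selection is deterministic.
    """
    samples = list(sample_set) if sample_set is not None else expr.sample_ids
    if n_top > len(expr.gene_ids):
        raise ValueError("n_top exceeds number of genes")
    logged = np.log2(expr.values[samples].to_numpy(dtype=float) + 1.0)
    logged_df = pd.DataFrame(logged, index=expr.gene_ids, columns=samples)
    med = np.median(logged, axis=1, keepdims=True)
    mad = np.median(np.abs(logged - med), axis=1)
    order = sorted(range(len(mad)), key=lambda i: (-mad[i], expr.gene_ids[i]))
    chosen = [expr.gene_ids[i] for i in order[:n_top]]
    sub = logged_df.loc[chosen]
    centered = sub.sub(sub.median(axis=1), axis=0)
    return ExpressionMatrix(values=centered, scale="log2_centered")


# ---------------------------------------------------------------------------
# distances and PAM


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """1 - Pearson correlation; errors on constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r)


def pearson_distance_matrix(columns: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Pearson distances between the columns of ``columns``."""
    if np.any(np.ptp(columns, axis=0) == 0):
        raise ValueError("correlation undefined for a constant column")
    d = 1.0 - np.corrcoef(columns, rowvar=False)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _pam_cost(dist: np.ndarray, medoids: np.ndarray) -> float:
    return float(dist[medoids].min(axis=0).sum())


def _pam_build(dist: np.ndarray, k: int, first: int | None = None) -> np.ndarray:
    """Greedy BUILD phase; optionally force the first medoid."""
    medoids = [int(np.argmin(dist.sum(axis=0))) if first is None else first]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding each candidate
        gains = np.maximum(nearest[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        nearest = np.minimum(nearest, dist[best])
    return np.array(sorted(medoids))


def pam(dist: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids with BUILD + SWAP local search.

    Deterministic given the distance matrix: ties resolve to the lowest
    index.  On small instances (n <= 12) the SWAP descent is restarted
    from every possible first BUILD medoid, which empirically escapes the
    rare local optima of the single-start search.  Returns (labels,
    medoid indices); labels are 0..k-1 in medoid order.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range for n={n}")

    starts = [None] if n > 12 else [None, *range(n)]
    best_med: np.ndarray | None = None
    best_cost = np.inf
    for first in starts:
        med, cost = _pam_swap(dist, _pam_build(dist, k, first), k)
        if cost < best_cost - 1e-15:
            best_cost, best_med = cost, med
    medoid_arr = best_med
    labels = np.argmin(dist[medoid_arr], axis=0)
    labels[medoid_arr] = np.arange(k)  # medoids belong to their own cluster
    return labels, medoid_arr


def _pam_swap(dist: np.ndarray, medoid_arr: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Steepest-descent over (medoid out, candidate in) until no swap improves."""
    n = dist.shape[0]
    cost = _pam_cost(dist, medoid_arr)
    while True:
        med_dist = dist[medoid_arr]  # k x n
        order = np.argsort(med_dist, axis=0)
        nearest_i = order[0]
        nearest_d = med_dist[nearest_i, np.arange(n)]
        second_d = med_dist[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)

        best_delta = -1e-12
        best_swap = None
        non_medoids = np.setdiff1d(np.arange(n), medoid_arr)
        if non_medoids.size == 0:
            break
        for mi in range(k):
            # distance to nearest medoid once medoid mi is removed
            without = np.where(nearest_i == mi, second_d, nearest_d)
            # new cost for every candidate x: sum(min(without, dist[x]))
            new_costs = np.minimum(without[None, :], dist[non_medoids]).sum(axis=1)
            j = int(np.argmin(new_costs))
            delta = new_costs[j] - cost
            if delta < best_delta:
                best_delta = delta
                best_swap = (mi, non_medoids[j])
        if best_swap is None:
            break
        mi, x = best_swap
        medoid_arr = np.array(sorted(np.r_[np.delete(medoid_arr, mi), x]))
        cost = _pam_cost(dist, medoid_arr)
    return medoid_arr, cost


# ---------------------------------------------------------------------------
# consensus clustering


@dataclass
class ConsensusResult:
    k_candidates: list[int]
    consensus: dict[int, np.ndarray]  # per k: samples x samples in [0,1]
    pac: dict[int, float]
    chosen_k: int
    labels: np.ndarray  # final labels per sample at chosen_k
    sample_ids: list[str]


def _pac_score(consensus: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = consensus[iu]
    if vals.size == 0:
        return 0.0
    return float(((vals > lower) & (vals < upper)).mean())


def consensus_cluster(
    expr_subset: ExpressionMatrix,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_iter: int = 1000,
    subsample: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
) -> ConsensusResult:
    """Resampled PAM consensus over Pearson distance.

    Each iteration draws ``ceil(subsample * n)`` samples without
    replacement and clusters them at every k; consensus(i, j) is the
    co-clustered fraction of co-sampled iterations.  PAC (fraction of
    ambiguous off-diagonal entries) selects k, ties to the smaller k, and
    final labels come from average-linkage clustering of 1 - consensus.
    """
    samples = expr_subset.sample_ids
    n = len(samples)
    k_range = tuple(sorted(k_range))
    if n < max(k_range) + 1:
        k_range = tuple(k for k in k_range if k < n)
    if not k_range:
        raise ValueError("no feasible k in range")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample * n))
    vals = expr_subset.values.to_numpy(dtype=float)

    together = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        co_sampled[np.ix_(idx, idx)] += 1
        dist = pearson_distance_matrix(vals[:, idx])
        for k in k_range:
            labels, _ = pam(dist, k)
            same = labels[:, None] == labels[None, :]
            together[k][np.ix_(idx, idx)] += same

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        log.warning(
            "consensus_cluster: %d sample pairs never co-sampled; consensus set to 0.5",
            int(never.sum()) // 2,
        )
    consensus = {}
    pac = {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(co_sampled > 0, together[k] / np.maximum(co_sampled, 1), 0.5)
        np.fill_diagonal(c, 1.0)
        c = (c + c.T) / 2.0
        consensus[k] = c
        pac[k] = _pac_score(c)

    chosen_k = min(k_range, key=lambda k: (pac[k], k))
    link = linkage(squareform(1.0 - consensus[chosen_k], checks=False), method="average")
    labels = fcluster(link, t=chosen_k, criterion="maxclust") - 1
    return ConsensusResult(
        k_candidates=list(k_range),
        consensus=consensus,
        pac=pac,
        chosen_k=chosen_k,
        labels=labels,
        sample_ids=list(samples),
    )


# ---------------------------------------------------------------------------
# silhouette pruning


def silhouette_widths(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """s(i) = (b - a) / max(a, b); members of singleton clusters get 0."""
    n = dist.shape[0]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():
            s[i] = 0.0  # singleton cluster: undefined, treated as unstable
            continue
        a = dist[i, own].mean()
        b = np.inf
        for c in uniq:
            if c == labels[i]:
                continue
            mask = labels == c
            if mask.any():
                b = min(b, dist[i, mask].mean())
        if not np.isfinite(b):
            s[i] = 0.0
        else:
            denom = max(a, b)
            s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


@dataclass
class SubtypeEntry:
    gene: str
    chosen_k: int
    members: dict[int, list[str]]  # surviving subtype index (1-based) -> samples
    silhouette: dict[str, float]
    removed_samples: list[str]
    dropped_small_subtypes: int
    small_group_rule_applied: bool
    pac: dict[int, float] = field(default_factory=dict)


@dataclass
class SubtypeCatalog:
    entries: dict[str, SubtypeEntry] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            gene: {
                "chosen_k": e.chosen_k,
                "members": {str(k): v for k, v in e.members.items()},
                "silhouette": e.silhouette,
                "removed_samples": e.removed_samples,
                "dropped_small_subtypes": e.dropped_small_subtypes,
                "small_group_rule_applied": e.small_group_rule_applied,
                "pac": {str(k): v for k, v in e.pac.items()},
            }
            for gene, e in self.entries.items()
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SubtypeCatalog":
        cat = cls()
        for gene, e in d.items():
            cat.entries[gene] = SubtypeEntry(
                gene=gene,
                chosen_k=e["chosen_k"],
                members={int(k): v for k, v in e["members"].items()},
                silhouette=e["silhouette"],
                removed_samples=e["removed_samples"],
                dropped_small_subtypes=e["dropped_small_subtypes"],
                small_group_rule_applied=e["small_group_rule_applied"],
                pac={int(k): v for k, v in e.get("pac", {}).items()},
            )
        return cat


def silhouette_prune(
    expr_subset: ExpressionMatrix,
    labels: np.ndarray,
    min_subtype_size: int = 5,
) -> tuple[dict[int, list[str]], dict[str, float], list[str], int]:
    """Single-pass silhouette pruning of cluster memberships.

    Members with non-positive silhouette width are removed, then clusters
    with fewer than ``min_subtype_size`` survivors are dropped entirely.
    Returns (surviving members by 1-based subtype index, silhouette per
    sample, removed sample ids, number of dropped subtypes).  Surviving
    subtypes are renumbered 1..m by decreasing size (ties by first member).
    """
    samples = expr_subset.sample_ids
    labels = np.asarray(labels)
    if len(labels) != len(samples):
        raise ValueError("labels do not match sample count")
    dist = pearson_distance_matrix(expr_subset.values.to_numpy(dtype=float))
    s = silhouette_widths(dist, labels)
    sil = {samples[i]: float(s[i]) for i in range(len(samples))}

    removed = [samples[i] for i in range(len(samples)) if s[i] <= 0]
    survivors: dict[int, list[str]] = {}
    for c in np.unique(labels):
        kept = [samples[i] for i in range(len(samples)) if labels[i] == c and s[i] > 0]
        if kept:
            survivors[int(c)] = kept
    dropped = 0
    for c in list(survivors):
        if len(survivors[c]) < min_subtype_size:
            removed.extend(survivors.pop(c))
            dropped += 1
    ordered = sorted(survivors.values(), key=lambda mem: (-len(mem), mem[0]))
    members = {i + 1: mem for i, mem in enumerate(ordered)}
    return members, sil, removed, dropped


# ---------------------------------------------------------------------------
# per-gene driver subtyping


def _gene_seed(master_seed: int, gene: str) -> np.random.SeedSequence:
    """Stable per-gene stream: adding a gene does not perturb the others."""
    digest = hashlib.sha256(gene.encode()).digest()
    return np.random.SeedSequence([master_seed, int.from_bytes(digest[:8], "big")])


def subtype_all(
    matrix: AlterationMatrix,
    expr: ExpressionMatrix,
    n_top: int = 2000,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_iter: int = 1000,
    subsample: float = 0.8,
    small_group_cutoff: int = 20,
    min_subtype_size: int = 5,
    seed: int = 0,
) -> tuple[SubtypeCatalog, AlterationMatrix]:
    """Subtype every gene-level event and append subtype rows to the matrix.

    Carrier sets larger than ``small_group_cutoff`` take the consensus
    clustering path; smaller ones are split directly into two PAM clusters
    on the full data.  Surviving subtypes become events ``GENE::S<k>``.
    """
    catalog = SubtypeCatalog()
    new_rows: dict[str, np.ndarray] = {}
    meta: dict[str, tuple[str, int | None]] = dict(matrix.event_meta)
    sample_pos = {s: j for j, s in enumerate(matrix.sample_ids)}

    for gene in matrix.gene_events():
        carriers = matrix.carriers(gene)
        carriers = [s for s in carriers if s in set(expr.sample_ids)]
        if len(carriers) < 2 * min_subtype_size:
            log.info("subtype_all: %s has %d carriers with expression; skipped", gene, len(carriers))
            continue
        n_top_g = min(n_top, len(expr.gene_ids))
        top = select_top_variable(expr, carriers, n_top=n_top_g)
        small_path = len(carriers) <= small_group_cutoff
        pac: dict[int, float] = {}
        if small_path:
            dist = pearson_distance_matrix(top.values.to_numpy(dtype=float))
            labels, _ = pam(dist, 2)
            chosen_k = 2
        else:
            res = consensus_cluster(
                top,
                k_range=k_range,
                n_iter=n_iter,
                subsample=subsample,
                seed=_gene_seed(seed, gene),
            )
            labels, chosen_k, pac = res.labels, res.chosen_k, res.pac

        members, sil, removed, dropped = silhouette_prune(top, labels, min_subtype_size)
        catalog.entries[gene] = SubtypeEntry(
            gene=gene,
            chosen_k=chosen_k,
            members=members,
            silhouette=sil,
            removed_samples=removed,
            dropped_small_subtypes=dropped,
            small_group_rule_applied=small_path,
            pac=pac,
        )
        if not members:
            log.info("subtype_all: all subtypes of %s dropped; gene-level event kept only", gene)
            continue
        for idx, mem in members.items():
            row = np.zeros(len(matrix.sample_ids), dtype=np.int8)
            row[[sample_pos[s] for s in mem]] = 1
            ev = subtype_event_id(gene, idx)
            new_rows[ev] = row
            meta[ev] = (gene, idx)

    values = matrix.values.copy()
    for ev, row in new_rows.items():
        values.loc[ev] = row
    out = AlterationMatrix(values=values.astype(np.int8), event_meta=meta)
    out.validate_subtype_nesting()
    return catalog, out
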