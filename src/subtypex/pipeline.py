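"""End-to-end orchestration: io -> subtyping -> exclusivity -> functions -> survival.

Every stage writes its outputs before the next starts, and a run manifest
records the config, per-stage counts, and sha256 checksums of all inputs
and outputs so a rerun with the same seed is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .exclusivity import (
    extend_background_to_subtypes,
    find_triples,
    fit_background,
    screen_pairs,
)
from .functions import de_test, enrich, filter_expressed, pair_functions, triple_functions, wildtype_samples
from .subtypes import SubtypeCatalog, subtype_all
from .survival import evaluate_triples

log = logging.getLogger("subtypex.pipeline")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    mutations: str = ""
    expression: str = ""
    clinical: str = ""
    driver_list: str = ""
    gene_sets: str = ""
    out_dir: str = "subtypex_out"

    min_carriers: int = 15
    top_n: int = 2000
    small_group_cutoff: int = 20
    min_subtype_size: int = 5
    q_threshold: float = 0.05
    de_log2fc: float = 1.0
    de_q: float = 0.05
    expr_min_count: int = 1
    expr_min_frac: float = 0.30

    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_iter: int = 1000
    subsample: float = 0.8
    seed: int = 0

    endpoint: str = "os"
    tie_method: str = "breslow"

    def validate(self) -> None:
        for name in ("min_carriers", "top_n", "small_group_cutoff", "min_subtype_size", "n_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        out = Path(self.out_dir).resolve()
        for p in (self.mutations, self.expression, self.clinical, self.driver_list, self.gene_sets):
            if p and Path(p).resolve() == out:
                raise ValueError("out_dir must be distinct from inputs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "k_range":
                val = tuple(val)
            setattr(cfg, key, val)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run the whole analysis; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "counts": {},
        "version": _package_version(),
    }
    for name in ("mutations", "expression", "clinical", "driver_list", "gene_sets"):
        p = Path(getattr(config, name))
        manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    t0 = time.time()

    # --- stage: io ----------------------------------------------------------
    records = sio.filter_nonsilent(sio.read_maf(config.mutations))
    expr = sio.read_expression(config.expression)
    clinical = sio.read_clinical(config.clinical)
    drivers = sio.read_driver_list(config.driver_list)
    gene_sets = sio.read_gmt(config.gene_sets)
    universe = sio.common_sample_universe(
        sorted({r.sample_id for r in records} | set(clinical.index)), expr.sample_ids
    )
    gene_matrix = sio.build_gene_matrix(records, drivers, universe)
    gene_matrix = sio.filter_min_carriers(gene_matrix, config.min_carriers)
    gene_matrix.write_tsv(out / "gene_matrix.tsv")
    emit("gene_matrix", out / "gene_matrix.tsv")
    manifest["counts"]["io"] = {
        "nonsilent_records": len(records),
        "samples": len(universe),
        "genes_kept": len(gene_matrix.event_ids),
    }
    log.info("[io] %d genes x %d samples (%.1fs)", len(gene_matrix.event_ids), len(universe), time.time() - t0)

    # --- stage: subtype -----------------------------------------------------
    catalog, full_matrix = subtype_all(
        gene_matrix,
        expr,
        n_top=min(config.top_n, len(expr.gene_ids)),
        k_range=config.k_range,
        n_iter=config.n_iter,
        subsample=config.subsample,
        small_group_cutoff=config.small_group_cutoff,
        min_subtype_size=config.min_subtype_size,
        seed=config.seed,
    )
    (out / "subtype_catalog.json").write_text(
        json.dumps(catalog.to_json_dict(), indent=1, sort_keys=True)
    )
    full_matrix.write_tsv(out / "event_matrix.tsv")
    emit("subtype_catalog", out / "subtype_catalog.json")
    emit("event_matrix", out / "event_matrix.tsv")
    n_subtypes = len(full_matrix.subtype_events())
    manifest["counts"]["subtype"] = {
        "genes_subtyped": len(catalog.entries),
        "subtypes": n_subtypes,
    }
    log.info("[subtype] %d subtype events (%.1fs)", n_subtypes, time.time() - t0)

    # --- stage: exclusivity -------------------------------------------------
    model = fit_background(gene_matrix)
    gene_pairs = screen_pairs(gene_matrix, model, level="gene", q_threshold=config.q_threshold)
    gene_pairs.to_csv(out / "pairs_gene.tsv", sep="\t", index=False)
    emit("pairs_gene", out / "pairs_gene.tsv")

    model_full = extend_background_to_subtypes(model, full_matrix)
    sub_pairs = screen_pairs(full_matrix, model_full, level="subtype", q_threshold=config.q_threshold)
    sub_pairs.to_csv(out / "pairs_subtype.tsv", sep="\t", index=False)
    emit("pairs_subtype", out / "pairs_subtype.tsv")

    triples = find_triples(sub_pairs, full_matrix, q_threshold=config.q_threshold)
    triples_df = pd.DataFrame(
        [
            {
                "event_a": t.events[0],
                "event_b": t.events[1],
                "event_c": t.events[2],
                "q_ab": t.pair_q_values[0],
                "q_ac": t.pair_q_values[1],
                "q_bc": t.pair_q_values[2],
            }
            for t in triples
        ],
        columns=["event_a", "event_b", "event_c", "q_ab", "q_ac", "q_bc"],
    )
    triples_df.to_csv(out / "triples.tsv", sep="\t", index=False)
    emit("triples", out / "triples.tsv")

    def _n_sig(df: pd.DataFrame, direction: str) -> int:
        return int(((df["direction"] == direction) & df["significant"]).sum())

    manifest["counts"]["exclusivity"] = {
        "gene_me_significant": _n_sig(gene_pairs, "mutual_exclusivity"),
        "gene_co_significant": _n_sig(gene_pairs, "co_occurrence"),
        "subtype_me_significant": _n_sig(sub_pairs, "mutual_exclusivity"),
        "subtype_co_significant": _n_sig(sub_pairs, "co_occurrence"),
        "triples": len(triples),
    }
    log.info(
        "[exclusivity] gene ME %d, subtype ME %d, triples %d (%.1fs)",
        manifest["counts"]["exclusivity"]["gene_me_significant"],
        manifest["counts"]["exclusivity"]["subtype_me_significant"],
        len(triples),
        time.time() - t0,
    )

    # --- stage: functions ---------------------------------------------------
    expr_f = filter_expressed(expr, config.expr_min_count, config.expr_min_frac)
    enrichment_tables: dict[str, pd.DataFrame] = {}
    de_counts: dict[str, int] = {}
    sig_me = sub_pairs[(sub_pairs["direction"] == "mutual_exclusivity") & sub_pairs["significant"]]
    needed = sorted(set(sig_me["event_a"]) | set(sig_me["event_b"]))
    for ev in needed:
        gene = full_matrix.gene_of(ev)
        members = full_matrix.carriers(ev)
        wt = wildtype_samples(full_matrix, [gene])
        members = [s for s in members if s in set(expr_f.sample_ids)]
        wt = [s for s in wt if s in set(expr_f.sample_ids)]
        if len(members) < 2 or len(wt) < 2:
            log.warning("[functions] %s skipped: group too small", ev)
            continue
        de = de_test(expr_f, members, wt, lfc_threshold=config.de_log2fc, q_threshold=config.de_q)
        degs = list(de.index[de["deg"]])
        de_counts[ev] = len(degs)
        de.to_csv(out / f"de_{ev.replace('::', '_')}.tsv", sep="\t")
        enrichment_tables[ev] = enrich(degs, gene_sets, list(expr_f.gene_ids), q_threshold=config.q_threshold)
        enrichment_tables[ev].to_csv(out / f"enrichment_{ev.replace('::', '_')}.tsv", sep="\t")

    pair_rows = []
    pair_sets: dict[frozenset[str], set[str]] = {}
    for _, row in sig_me.iterrows():
        a, b = row["event_a"], row["event_b"]
        if a not in enrichment_tables or b not in enrichment_tables:
            continue
        terms = pair_functions((a, b), enrichment_tables)
        pair_sets[frozenset((a, b))] = terms
        pair_rows.append({"event_a": a, "event_b": b, "terms": ";".join(sorted(terms))})
    pd.DataFrame(pair_rows, columns=["event_a", "event_b", "terms"]).to_csv(
        out / "pair_functions.tsv", sep="\t", index=False
    )
    emit("pair_functions", out / "pair_functions.tsv")

    triple_rows = []
    for t in triples:
        a, b, c = t.events
        keys = [frozenset((a, b)), frozenset((a, c)), frozenset((b, c))]
        if all(k in pair_sets for k in keys):
            terms = triple_functions([pair_sets[k] for k in keys])
            triple_rows.append({"triple": "|".join(t.events), "terms": ";".join(sorted(terms))})
    pd.DataFrame(triple_rows, columns=["triple", "terms"]).to_csv(
        out / "triple_functions.tsv", sep="\t", index=False
    )
    emit("triple_functions", out / "triple_functions.tsv")
    manifest["counts"]["functions"] = {
        "events_tested": len(enrichment_tables),
        "pairs_with_functions": len(pair_rows),
        "triples_with_functions": len(triple_rows),
    }
    log.info("[functions] %d events tested (%.1fs)", len(enrichment_tables), time.time() - t0)

    # --- stage: survival ----------------------------------------------------
    if triples:
        surv = evaluate_triples(
            triples,
            full_matrix,
            catalog,
            clinical,
            endpoint=config.endpoint,
            ties=config.tie_method,
        )
    else:
        surv = pd.DataFrame()
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    emit("survival", out / "survival.tsv")
    manifest["counts"]["survival"] = {
        "triples_evaluated": int(len(surv)),
        "logrank_significant": int((surv["logrank_p"] < 0.05).sum()) if len(surv) else 0,
        "independent_predictors": int(surv["independent_predictor"].sum()) if len(surv) else 0,
    }
    log.info("[survival] %d triples evaluated (%.1fs)", len(surv), time.time() - t0)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _package_version() -> str:
    from . import __version__

    return __version__
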