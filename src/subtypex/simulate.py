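"""Synthetic tumor cohorts with planted subtype structure and ground truth.

The generator mirrors the assumptions of the analysis: heterogeneous
per-sample mutation loads and per-gene rates (logistic margins), latent
expression subtypes inside each driver's carrier set realised as negative
binomial mean shifts on dedicated gene blocks, mutual exclusivity planted
at the subtype level, and exponential survival with an elevated hazard for
carriers of the planted triple.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import MutationRecord, ExpressionMatrix, VariantClass, NONSILENT_CLASSES, write_gmt
from .io import subtype_event_id

log = logging.getLogger("subtypex.simulate")

__all__ = [
    "SubtypeSpec",
    "MEPlant",
    "COPlant",
    "TriplePlant",
    "SurvivalSpec",
    "SimConfig",
    "SyntheticTruth",
    "CohortBundle",
    "simulate_cohort",
    "write_cohort",
    "default_config",
    "recovery_config",
    "null_config",
]


@dataclass
class SubtypeSpec:
    k: int = 2
    proportions: tuple[float, ...] = (0.5, 0.5)
    de_block_size: int = 100
    log2_effect: float = 2.0

    def validate(self) -> None:
        if len(self.proportions) != self.k:
            raise ValueError("proportions length must equal k")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


@dataclass
class MEPlant:
    gene_a: str
    subtype_index: int  # 1-based designated subtype of gene_a
    gene_b: str
    epsilon: float = 0.0  # P(B | in subtype) / P(B | otherwise), in [0, 1)

    def validate(self) -> None:
        if not (0.0 <= self.epsilon < 1.0):
            raise ValueError("epsilon must lie in [0, 1)")


@dataclass
class COPlant:
    gene_a: str
    subtype_index: int
    gene_b: str
    factor: float = 3.0  # enrichment multiplier, > 1

    def validate(self) -> None:
        if self.factor <= 1.0:
            raise ValueError("co-occurrence factor must exceed 1")


@dataclass
class TriplePlant:
    genes: tuple[str, str, str]
    subtype_indices: tuple[int, int, int] = (1, 1, 1)
    epsilon: float = 0.0


@dataclass
class SurvivalSpec:
    baseline_hazard: float = 1.0 / 1000.0  # per day
    triple_hazard_ratio: float = 2.0
    censoring_rate: float = 0.3  # expected censored fraction under the baseline


@dataclass
class SimConfig:
    n_samples: int = 300
    n_genes_expr: int = 2000
    n_driver_genes: int = 12
    carrier_rate_range: tuple[float, float] = (0.10, 0.35)
    carrier_rates: dict[str, float] = field(default_factory=dict)  # per-gene overrides
    load_sigma: float = 0.5  # sd of per-sample log-load multiplier
    subtype_specs: dict[str, SubtypeSpec] = field(default_factory=dict)
    planted_me: list[MEPlant] = field(default_factory=list)
    planted_co: list[COPlant] = field(default_factory=list)
    planted_triple: TriplePlant | None = None
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    nb_dispersion_range: tuple[float, float] = (0.05, 0.2)
    base_mean_range: tuple[float, float] = (20.0, 500.0)
    n_decoy_terms: int = 30
    decoy_term_size: tuple[int, int] = (10, 200)
    seed: int = 0

    def driver_names(self) -> list[str]:
        return [f"DRV{i + 1:02d}" for i in range(self.n_driver_genes)]

    def validate(self) -> None:
        if self.survival.triple_hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")
        drivers = set(self.driver_names())
        for g, spec in self.subtype_specs.items():
            if g not in drivers:
                raise ValueError(f"subtype spec for unknown driver {g}")
            spec.validate()
        for plant in self.planted_me:
            plant.validate()
            self._check_plant_genes(plant.gene_a, plant.subtype_index, plant.gene_b, drivers)
        for plant in self.planted_co:
            plant.validate()
            self._check_plant_genes(plant.gene_a, plant.subtype_index, plant.gene_b, drivers)
        if self.planted_triple is not None:
            t = self.planted_triple
            if len(set(t.genes)) != 3:
                raise ValueError("triple genes must be distinct")
            for g, si in zip(t.genes, t.subtype_indices):
                self._check_plant_genes(g, si, t.genes[0] if g != t.genes[0] else t.genes[1], drivers)

    def _check_plant_genes(self, gene_a: str, subtype_index: int, gene_b: str, drivers: set) -> None:
        if gene_a not in drivers or gene_b not in drivers:
            raise ValueError(f"planted pair references unknown driver ({gene_a}, {gene_b})")
        spec = self.subtype_specs.get(gene_a)
        if spec is None:
            raise ValueError(f"gene {gene_a} has no subtype spec but is used in a plant")
        if not (1 <= subtype_index <= spec.k):
            raise ValueError(f"subtype index {subtype_index} out of range for {gene_a}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        cfg = cls()
        for key in (
            "n_samples",
            "n_genes_expr",
            "n_driver_genes",
            "load_sigma",
            "n_decoy_terms",
            "seed",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        for key in ("carrier_rate_range", "nb_dispersion_range", "base_mean_range", "decoy_term_size"):
            if key in raw:
                setattr(cfg, key, tuple(raw[key]))
        for g, s in raw.get("subtype_specs", {}).items():
            cfg.subtype_specs[g] = SubtypeSpec(
                k=s.get("k", 2),
                proportions=tuple(s.get("proportions", (0.5, 0.5))),
                de_block_size=s.get("de_block_size", 100),
                log2_effect=s.get("log2_effect", 2.0),
            )
        for p in raw.get("planted_me", []):
            cfg.planted_me.append(MEPlant(**p))
        for p in raw.get("planted_co", []):
            cfg.planted_co.append(COPlant(**p))
        if raw.get("planted_triple"):
            t = raw["planted_triple"]
            cfg.planted_triple = TriplePlant(
                genes=tuple(t["genes"]),
                subtype_indices=tuple(t.get("subtype_indices", (1, 1, 1))),
                epsilon=t.get("epsilon", 0.0),
            )
        if "survival" in raw:
            cfg.survival = SurvivalSpec(**raw["survival"])
        return cfg


@dataclass
class SyntheticTruth:
    subtype_labels: dict[str, dict[str, int]]  # gene -> sample -> 1-based subtype
    planted_me_events: list[tuple[str, str]]  # (subtype event of A, gene B)
    planted_co_events: list[tuple[str, str]]
    planted_triple_events: tuple[str, str, str] | None
    de_blocks: dict[str, list[str]]  # subtype event -> expression genes
    true_terms: dict[str, str]  # subtype event -> enriched term id
    hazard_ratio: float

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["planted_me_events"] = [list(t) for t in self.planted_me_events]
        d["planted_co_events"] = [list(t) for t in self.planted_co_events]
        if self.planted_triple_events is not None:
            d["planted_triple_events"] = list(self.planted_triple_events)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            subtype_labels={g: {s: int(v) for s, v in m.items()} for g, m in d["subtype_labels"].items()},
            planted_me_events=[tuple(t) for t in d["planted_me_events"]],
            planted_co_events=[tuple(t) for t in d["planted_co_events"]],
            planted_triple_events=(
                tuple(d["planted_triple_events"]) if d.get("planted_triple_events") else None
            ),
            de_blocks=d["de_blocks"],
            true_terms=d["true_terms"],
            hazard_ratio=d["hazard_ratio"],
        )


@dataclass
class CohortBundle:
    mutations: list[MutationRecord]
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    gene_sets: dict[str, list[str]]
    driver_genes: list[str]
    truth: SyntheticTruth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _plant_order(config: SimConfig) -> list[str]:
    """Topological order so suppression sources are drawn before targets."""
    drivers = config.driver_names()
    edges: list[tuple[str, str]] = []
    for p in config.planted_me + config.planted_co:
        edges.append((p.gene_a, p.gene_b))
    if config.planted_triple is not None:
        a, b, c = config.planted_triple.genes
        edges += [(a, b), (a, c), (b, c)]
    order: list[str] = []
    remaining = set(drivers)
    while remaining:
        free = sorted(
            g for g in remaining if not any(src in remaining and dst == g for src, dst in edges)
        )
        if not free:
            raise ValueError("planted exclusivity graph contains a cycle")
        order.extend(free)
        remaining -= set(free)
    return order


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Draw one cohort under ``config``; fully reproducible given its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    drivers = config.driver_names()
    expr_genes = [f"G{i + 1:05d}" for i in range(config.n_genes_expr)]

    # per-sample mutation-load multipliers (log scale)
    load = rng.normal(0.0, config.load_sigma, size=n)

    # per-gene base rates; feasibility check before any carrier is drawn
    lo, hi = config.carrier_rate_range
    rates = {g: rng.uniform(lo, hi) for g in drivers}
    rates.update({g: r for g, r in config.carrier_rates.items() if g in rates})
    for g, spec in config.subtype_specs.items():
        expected_min = rates[g] * n * min(spec.proportions)
        if expected_min < 5:
            raise ValueError(
                f"infeasible config: gene {g} expects {expected_min:.1f} carriers "
                "in its smallest subtype (< 5)"
            )

    # planted suppression/enrichment, keyed by target gene
    me_by_target: dict[str, list[tuple[str, int, float]]] = {}
    co_by_target: dict[str, list[tuple[str, int, float]]] = {}
    for p in config.planted_me:
        me_by_target.setdefault(p.gene_b, []).append((p.gene_a, p.subtype_index, p.epsilon))
    for p in config.planted_co:
        co_by_target.setdefault(p.gene_b, []).append((p.gene_a, p.subtype_index, p.factor))
    if config.planted_triple is not None:
        t = config.planted_triple
        (a, sa), (b, sb), (c, sc) = zip(t.genes, t.subtype_indices)
        me_by_target.setdefault(b, []).append((a, sa, t.epsilon))
        me_by_target.setdefault(c, []).append((a, sa, t.epsilon))
        me_by_target.setdefault(c, []).append((b, sb, t.epsilon))

    carrier: dict[str, np.ndarray] = {}
    subtype_labels: dict[str, dict[str, int]] = {}
    label_arrays: dict[str, np.ndarray] = {}  # -1 for non-carriers

    for gene in _plant_order(config):
        probs = _sigmoid(_logit(rates[gene]) + load)
        for src, s_idx, eps in me_by_target.get(gene, []):
            in_sub = label_arrays[src] == s_idx
            probs = np.where(in_sub, probs * eps, probs)
        for src, s_idx, factor in co_by_target.get(gene, []):
            in_sub = label_arrays[src] == s_idx
            probs = np.where(in_sub, np.minimum(probs * factor, 1.0), probs)
        mutated = rng.random(n) < probs
        carrier[gene] = mutated

        labels = np.full(n, -1, dtype=int)
        spec = config.subtype_specs.get(gene)
        if spec is not None:
            idx = np.where(mutated)[0]
            assignments = rng.choice(np.arange(1, spec.k + 1), size=idx.size, p=spec.proportions)
            labels[idx] = assignments
            subtype_labels[gene] = {samples[i]: int(labels[i]) for i in idx}
        label_arrays[gene] = labels

    # expression: NB counts with subtype-specific mean shifts on disjoint blocks
    base_mean = np.exp(rng.uniform(*np.log(config.base_mean_range), size=config.n_genes_expr))
    dispersion = np.exp(rng.uniform(*np.log(config.nb_dispersion_range), size=config.n_genes_expr))
    mean = np.tile(base_mean[:, None], (1, n))

    de_blocks: dict[str, list[str]] = {}
    next_block_start = 0
    for gene in drivers:
        spec = config.subtype_specs.get(gene)
        if spec is None:
            continue
        for s_idx in range(1, spec.k + 1):
            block = slice(next_block_start, next_block_start + spec.de_block_size)
            if block.stop > config.n_genes_expr:
                raise ValueError("not enough expression genes for all DE blocks")
            next_block_start = block.stop
            in_sub = label_arrays[gene] == s_idx
            mean[block, :][:, in_sub] *= 2.0 ** spec.log2_effect
            de_blocks[subtype_event_id(gene, s_idx)] = expr_genes[block]

    # NB(mean mu, dispersion alpha): shape r = 1/alpha, p = r/(r+mu)
    r_shape = 1.0 / dispersion[:, None]
    counts = rng.negative_binomial(r_shape, r_shape / (r_shape + mean))
    expression = ExpressionMatrix(
        values=pd.DataFrame(counts, index=expr_genes, columns=samples), scale="raw_counts"
    )

    # gene sets: one true term per DE block plus random decoys
    gene_sets: dict[str, list[str]] = {}
    true_terms: dict[str, str] = {}
    for ev, block in de_blocks.items():
        extra = rng.choice(expr_genes, size=10, replace=False).tolist()
        term = f"TERM_TRUE_{ev.replace('::', '_')}"
        gene_sets[term] = sorted(set(block) | set(extra))
        true_terms[ev] = term
    size_lo, size_hi = config.decoy_term_size
    size_hi = min(size_hi, config.n_genes_expr)
    size_lo = min(size_lo, size_hi)
    for i in range(config.n_decoy_terms):
        size = int(rng.integers(size_lo, size_hi + 1))
        gene_sets[f"TERM_DECOY_{i + 1:03d}"] = sorted(
            rng.choice(expr_genes, size=size, replace=False).tolist()
        )

    # mutation records: one non-silent record per carrier plus silent noise
    nonsilent = sorted(NONSILENT_CLASSES, key=lambda v: v.value)
    records: list[MutationRecord] = []
    for gene in drivers:
        for i in np.where(carrier[gene])[0]:
            vc = nonsilent[rng.integers(0, len(nonsilent))]
            records.append(MutationRecord(samples[i], gene, vc))
    n_silent = max(1, n // 10)
    for i in rng.choice(n, size=n_silent, replace=False):
        g = drivers[rng.integers(0, len(drivers))]
        records.append(MutationRecord(samples[i], g, VariantClass.SILENT))

    # survival: exponential with elevated hazard for planted-triple carriers
    triple_events: tuple[str, str, str] | None = None
    in_triple = np.zeros(n, dtype=bool)
    if config.planted_triple is not None:
        t = config.planted_triple
        triple_events = tuple(
            subtype_event_id(g, si) for g, si in zip(t.genes, t.subtype_indices)
        )
        for g, si in zip(t.genes, t.subtype_indices):
            in_triple |= label_arrays[g] == si
    hr = config.survival.triple_hazard_ratio
    h0 = config.survival.baseline_hazard
    hazard = np.where(in_triple, h0 * hr, h0)
    cens_frac = config.survival.censoring_rate
    cens_rate = h0 * cens_frac / max(1.0 - cens_frac, 1e-9)

    clinical = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    for prefix in ("os", "dss"):
        t_event = rng.exponential(1.0 / hazard)
        t_cens = rng.exponential(1.0 / cens_rate, size=n) if cens_rate > 0 else np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        clinical[f"{prefix}_time"] = np.round(time, 1)
        clinical[f"{prefix}_event"] = (t_event <= t_cens).astype(int)
    clinical["age"] = np.round(rng.normal(65, 9, size=n), 1)
    clinical["gender"] = rng.choice(["female", "male"], size=n)
    clinical["ajcc_stage"] = rng.choice(
        ["I", "II", "III", "IV"], size=n, p=[0.5, 0.25, 0.2, 0.05]
    )
    clinical["t_stage"] = rng.choice(["T1", "T2", "T3", "T4"], size=n, p=[0.3, 0.5, 0.15, 0.05])
    clinical["n_stage"] = rng.choice(["N0", "N1", "N2", "N3"], size=n, p=[0.65, 0.2, 0.13, 0.02])

    truth = SyntheticTruth(
        subtype_labels=subtype_labels,
        planted_me_events=[
            (subtype_event_id(p.gene_a, p.subtype_index), p.gene_b) for p in config.planted_me
        ],
        planted_co_events=[
            (subtype_event_id(p.gene_a, p.subtype_index), p.gene_b) for p in config.planted_co
        ],
        planted_triple_events=triple_events,
        de_blocks=de_blocks,
        true_terms=true_terms,
        hazard_ratio=hr,
    )
    return CohortBundle(
        mutations=records,
        expression=expression,
        clinical=clinical,
        gene_sets=gene_sets,
        driver_genes=drivers,
        truth=truth,
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort as plain-text files readable by the io layer."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out}") from exc

    paths = {
        "mutations": out / "mutations.maf.tsv",
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "drivers": out / "drivers.txt",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    maf = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": [r.sample_id for r in bundle.mutations],
            "Hugo_Symbol": [r.gene for r in bundle.mutations],
            "Variant_Classification": [r.variant_class.value for r in bundle.mutations],
        }
    )
    maf.to_csv(paths["mutations"], sep="\t", index=False)
    bundle.expression.write_tsv(paths["expression"])
    bundle.clinical.to_csv(paths["clinical"], sep="\t")
    paths["drivers"].write_text("\n".join(bundle.driver_genes) + "\n")
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    paths["truth"].write_text(json.dumps(bundle.truth.to_json_dict(), indent=1, sort_keys=True))
    return paths


def default_config(seed: int = 0) -> SimConfig:
    """Small cohort with two planted ME pairs, one CO pair, and a triple."""
    cfg = SimConfig(seed=seed)
    for g in ("DRV01", "DRV02", "DRV03", "DRV04", "DRV05", "DRV09"):
        cfg.subtype_specs[g] = SubtypeSpec(k=2, proportions=(0.5, 0.5), de_block_size=100, log2_effect=2.0)
    cfg.planted_me = [
        MEPlant(gene_a="DRV01", subtype_index=1, gene_b="DRV06", epsilon=0.0),
        MEPlant(gene_a="DRV02", subtype_index=2, gene_b="DRV07", epsilon=0.0),
    ]
    cfg.planted_co = [COPlant(gene_a="DRV03", subtype_index=1, gene_b="DRV08", factor=3.0)]
    cfg.planted_triple = TriplePlant(genes=("DRV04", "DRV05", "DRV09"), subtype_indices=(1, 1, 1))
    return cfg


def recovery_config(seed: int = 0) -> SimConfig:
    """Planted-structure recovery scenario.

    Exclusivity is restricted to one small subtype of each source gene
    (20% of carriers), so the gene-level pair signal stays diluted while
    the subtype-level pairs are strongly powered.  Several pairs are
    planted so the FDR correction adapts as it would on dense real data.
    """
    cfg = SimConfig(
        n_samples=800,
        n_genes_expr=2400,
        n_driver_genes=32,
        carrier_rate_range=(0.25, 0.50),
        load_sigma=0.3,
        seed=seed,
    )
    source = "DRV01"
    targets = ("DRV02", "DRV03", "DRV04", "DRV05")
    # filler genes stabilize the per-sample load estimates of the background
    # model without contributing expression structure
    cfg.carrier_rates = {f"DRV{i:02d}": 0.10 for i in range(6, 33)}
    cfg.carrier_rates[source] = 0.50
    cfg.carrier_rates.update({g: 0.5 for g in targets})
    cfg.subtype_specs[source] = SubtypeSpec(
        k=2, proportions=(0.13, 0.87), de_block_size=200, log2_effect=2.0
    )
    for g in targets:
        cfg.subtype_specs[g] = SubtypeSpec(
            k=2, proportions=(0.5, 0.5), de_block_size=200, log2_effect=2.0
        )
    cfg.planted_me = [
        MEPlant(gene_a=source, subtype_index=1, gene_b=b, epsilon=0.0) for b in targets
    ]
    return cfg


def null_config(seed: int = 0, n_samples: int = 300, n_driver_genes: int = 24) -> SimConfig:
    """No planted structure: heterogeneous rates and loads only."""
    return SimConfig(
        n_samples=n_samples,
        n_genes_expr=500,
        n_driver_genes=n_driver_genes,
        carrier_rate_range=(0.10, 0.35),
        load_sigma=0.6,
        seed=seed,
    )
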