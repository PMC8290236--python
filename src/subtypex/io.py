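"""Reading standard inputs, mutation filters, and the binary alteration matrix.

Events are either whole genes (``"TP53"``) or gene subtypes
(``"TP53::S2"``).  All downstream statistics operate on the binary
events-by-samples matrix built here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("subtypex.io")

__all__ = [
    "VariantClass",
    "MutationRecord",
    "AlterationMatrix",
    "ExpressionMatrix",
    "NONSILENT_CLASSES",
    "read_maf",
    "filter_nonsilent",
    "build_gene_matrix",
    "filter_min_carriers",
    "read_expression",
    "read_clinical",
    "read_driver_list",
    "read_gmt",
    "write_gmt",
]


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    TRANSLATION_START_SITE = "translation_start_site"
    IN_FRAME_DEL = "in_frame_del"
    IN_FRAME_INS = "in_frame_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    FRAMESHIFT_INS = "frameshift_ins"
    SPLICE_SITE = "splice_site"
    NONSTOP = "nonstop"
    SILENT = "silent"
    OTHER = "other"


#: the nine protein-altering classes retained by the mutation filter
NONSILENT_CLASSES = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.TRANSLATION_START_SITE,
        VariantClass.IN_FRAME_DEL,
        VariantClass.IN_FRAME_INS,
        VariantClass.FRAMESHIFT_DEL,
        VariantClass.FRAMESHIFT_INS,
        VariantClass.SPLICE_SITE,
        VariantClass.NONSTOP,
    }
)

# GDC MAF spellings -> internal enum
_CLASS_MAP: dict[str, VariantClass] = {
    "missense_mutation": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "translation_start_site": VariantClass.TRANSLATION_START_SITE,
    "in_frame_del": VariantClass.IN_FRAME_DEL,
    "in_frame_ins": VariantClass.IN_FRAME_INS,
    "frame_shift_del": VariantClass.FRAMESHIFT_DEL,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INS,
    "splice_site": VariantClass.SPLICE_SITE,
    "nonstop_mutation": VariantClass.NONSTOP,
    "silent": VariantClass.SILENT,
    # already-canonical spellings round-trip
    **{v.value: v for v in VariantClass},
}


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    gene: str
    variant_class: VariantClass

    def __post_init__(self) -> None:
        if not self.sample_id or not self.gene:
            raise ValueError("sample_id and gene must be non-empty")


@dataclass
class AlterationMatrix:
    """Binary events x samples matrix with per-event metadata.

    ``event_meta`` maps event id -> (gene, subtype_index), where
    subtype_index is ``None`` for gene-level events.
    """

    values: pd.DataFrame  # events x samples, dtype int8, entries in {0,1}
    event_meta: dict[str, tuple[str, int | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate event ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        self.values = self.values.astype(np.int8)
        for ev in self.values.index:
            self.event_meta.setdefault(ev, parse_event_id(ev))

    @property
    def event_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def carriers(self, event_id: str) -> list[str]:
        row = self.values.loc[event_id]
        return list(row.index[row.to_numpy().astype(bool)])

    def carrier_counts(self) -> pd.Series:
        return self.values.sum(axis=1)

    def gene_of(self, event_id: str) -> str:
        return self.event_meta[event_id][0]

    def is_subtype_event(self, event_id: str) -> bool:
        return self.event_meta[event_id][1] is not None

    def gene_events(self) -> list[str]:
        return [e for e in self.event_ids if not self.is_subtype_event(e)]

    def subtype_events(self) -> list[str]:
        return [e for e in self.event_ids if self.is_subtype_event(e)]

    def validate_subtype_nesting(self) -> None:
        """Subtype rows of one gene must be disjoint subsets of the gene row."""
        vals = self.values
        by_gene: dict[str, list[str]] = {}
        for ev in self.subtype_events():
            by_gene.setdefault(self.gene_of(ev), []).append(ev)
        for gene, evs in by_gene.items():
            sub = vals.loc[evs].to_numpy()
            if sub.sum(axis=0).max(initial=0) > 1:
                raise ValueError(f"subtype events of {gene} are not disjoint")
            if gene in vals.index:
                parent = vals.loc[gene].to_numpy()
                if np.any(sub > parent[None, :]):
                    raise ValueError(
                        f"subtype event of {gene} is not a subset of the gene row"
                    )

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="event_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AlterationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns = df.columns.astype(str)
        return cls(values=df)


_EVENT_RE = re.compile(r"^(?P<gene>.+)::S(?P<idx>\d+)$")


def parse_event_id(event_id: str) -> tuple[str, int | None]:
    m = _EVENT_RE.match(event_id)
    if m:
        return m.group("gene"), int(m.group("idx"))
    return event_id, None


def subtype_event_id(gene: str, index: int) -> str:
    return f"{gene}::S{index}"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``scale`` is ``"raw_counts"`` (non-negative) or ``"log2_centered"``
    (per-gene median zero).
    """

    values: pd.DataFrame
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.scale not in ("raw_counts", "log2_centered"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw_counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.scale == "log2_centered" and len(self.values.columns):
            med = self.values.median(axis=1).to_numpy()
            if np.abs(med).max(initial=0.0) > 1e-9:
                raise ValueError("log2_centered rows must have median 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str | Path, scale: str = "raw_counts") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df, scale=scale)


CLINICAL_COLUMNS = [
    "os_time",
    "os_event",
    "dss_time",
    "dss_event",
    "age",
    "gender",
    "ajcc_stage",
    "t_stage",
    "n_stage",
]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical table indexed by sample id; missing fields stay NaN."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in ("os_time", "dss_time"):
        if col in df and (df[col].dropna() < 0).any():
            raise ValueError(f"{col} contains negative times")
    for col in ("os_event", "dss_event"):
        if col in df and not df[col].dropna().isin((0, 1)).all():
            raise ValueError(f"{col} must be 0/1")
    return df


def read_driver_list(path: str | Path) -> list[str]:
    genes = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [g for g in genes if g and not g.startswith("#")]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {ln[:80]!r}")
        sets[parts[0]] = parts[2:]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            fh.write("\t".join([term, term, *genes]) + "\n")


def read_maf(
    path: str | Path,
    sample_col: str = "Tumor_Sample_Barcode",
    gene_col: str = "Hugo_Symbol",
    class_col: str = "Variant_Classification",
    barcode_normalizer: "callable | None" = None,
) -> list[MutationRecord]:
    """Parse a MAF-like TSV into mutation records.

    Column names default to the GDC dialect and are configurable for
    legacy files.  Unknown classification strings map to ``other`` with a
    warning.  ``barcode_normalizer``, off by default, maps raw sample
    barcodes to analysis ids (e.g. truncating aliquot-level barcodes to
    the patient level).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (sample_col, gene_col, class_col):
        if col not in df.columns:
            raise ValueError(f"required MAF column missing: {col!r}")
    records: list[MutationRecord] = []
    unknown: set[str] = set()
    for sample, gene, cls in zip(df[sample_col], df[gene_col], df[class_col]):
        if barcode_normalizer is not None:
            sample = barcode_normalizer(str(sample))
        key = str(cls).strip().lower()
        vc = _CLASS_MAP.get(key)
        if vc is None:
            unknown.add(str(cls))
            vc = VariantClass.OTHER
        records.append(MutationRecord(str(sample), str(gene), vc))
    if unknown:
        log.warning(
            "mapped %d unknown variant classification(s) to 'other': %s",
            len(unknown),
            sorted(unknown),
        )
    return records


def filter_nonsilent(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Keep only the nine protein-altering classes (drops silent/other)."""
    return [r for r in records if r.variant_class in NONSILENT_CLASSES]


def build_gene_matrix(
    records: Iterable[MutationRecord],
    driver_genes: Sequence[str],
    samples: Sequence[str],
) -> AlterationMatrix:
    """Binary gene x sample incidence over the driver list and sample universe.

    Multiple mutations of one gene in one sample collapse to a single 1.
    """
    driver_genes = list(dict.fromkeys(driver_genes))
    if not driver_genes:
        raise ValueError("driver gene list is empty")
    samples = list(dict.fromkeys(samples))
    gene_idx = {g: i for i, g in enumerate(driver_genes)}
    samp_idx = {s: j for j, s in enumerate(samples)}
    vals = np.zeros((len(driver_genes), len(samples)), dtype=np.int8)
    for r in records:
        gi = gene_idx.get(r.gene)
        sj = samp_idx.get(r.sample_id)
        if gi is not None and sj is not None:
            vals[gi, sj] = 1
    df = pd.DataFrame(vals, index=driver_genes, columns=samples)
    return AlterationMatrix(values=df)


def filter_min_carriers(matrix: AlterationMatrix, min_carriers: int = 15) -> AlterationMatrix:
    """Keep events mutated in strictly more than ``min_carriers`` samples."""
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    keep = matrix.values.sum(axis=1) > min_carriers
    kept = matrix.values.loc[keep]
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_min_carriers: dropped %d events (<= %d carriers)", dropped, min_carriers)
    meta = {e: matrix.event_meta[e] for e in kept.index}
    return AlterationMatrix(values=kept.copy(), event_meta=meta)


def common_sample_universe(
    mutation_samples: Iterable[str], expression_samples: Iterable[str]
) -> list[str]:
    """Samples present in both mutation and expression data (analysis universe)."""
    expr = set(expression_samples)
    universe = [s for s in dict.fromkeys(mutation_samples) if s in expr]
    n_dropped = len(set(mutation_samples) | expr) - len(universe)
    if n_dropped:
        log.info("sample universe: %d samples retained, %d dropped", len(universe), n_dropped)
    return universe
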