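# subtypex

Subtype-conditioned mutual-exclusivity analysis of driver gene mutations.

Tumors carrying mutations in the same driver gene are often transcriptomically
heterogeneous. `subtypex` splits each driver gene's carriers into expression
subtypes (consensus PAM clustering with silhouette pruning), treats each
subtype as its own binary alteration event, and tests all event pairs for
mutual exclusivity or co-occurrence against a maximum-entropy background model
with an exact Poisson-binomial overlap test. Exclusive pairs and triples are
annotated with biological functions via differential expression plus gene-set
enrichment intersection, and exclusive triples are evaluated for prognostic
value with Kaplan–Meier/log-rank and Cox models. A synthetic-cohort generator
with planted ground truth makes every stage testable offline.

## Layout

| Module | Role |
| --- | --- |
| `subtypex.io` | MAF/expression/clinical/GMT readers, mutation filters, binary alteration matrix |
| `subtypex.simulate` | Synthetic cohorts with planted subtypes, exclusivity, and survival effects |
| `subtypex.subtypes` | MAD gene selection, PAM, consensus clustering (PAC), silhouette pruning |
| `subtypex.exclusivity` | Margin-constrained background model, Poisson-binomial ME/CO tests, BH, triples |
| `subtypex.functions` | Expression filter, NB Wald differential expression, hypergeometric enrichment, pair/triple function intersection |
| `subtypex.survival` | Kaplan–Meier, log-rank, Cox PH (Breslow/Efron), triple evaluation |
| `subtypex.pipeline` | End-to-end orchestration with a run manifest (checksums, counts) |

## CLI

```bash
# generate a synthetic cohort (MAF-like TSV, expression TSV, clinical TSV, GMT, truth JSON)
subtypex simulate --out cohort/ --seed 7

# discover subtypes and append subtype events to the alteration matrix
subtypex subtype --expr cohort/expression.tsv --matrix events.tsv \
    --out catalog.json --events-out events_full.tsv --n-iter 1000 --seed 7

# screen pairs for mutual exclusivity / co-occurrence, enumerate triples
subtypex exclusivity --matrix events_full.tsv --level subtype --q 0.05 \
    --out pairs.tsv --triples-out triples.tsv

# prognostic evaluation of exclusive triples
subtypex survival --triples triples.tsv --matrix events_full.tsv \
    --catalog catalog.json --clinical cohort/clinical.tsv --endpoint os --out surv.tsv

# everything at once from a YAML config
subtypex run-all --config config.yaml
```

A minimal `config.yaml` for `run-all`:

```yaml
mutations: cohort/mutations.maf.tsv
expression: cohort/expression.tsv
clinical: cohort/clinical.tsv
driver_list: cohort/drivers.txt
gene_sets: cohort/gene_sets.gmt
out_dir: out/
n_iter: 1000
k_range: [2, 3, 4, 5, 6]
seed: 7
```

Defaults follow the published analysis: non-silent mutation classes only,
events kept above 15 carriers, top 2000 MAD genes, 80% resampling over the
consensus iterations, subtypes below 5 members dropped, q < 0.05, DEG at
|log2FC| ≥ 1 and FDR < 0.05, genes expressed at count > 1 in ≥ 30% of samples.

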