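# ptmlri

Ligand–receptor interaction (LRI) inference from two-cluster differential
proteomics, refined with site-level post-translational modification (PTM)
evidence.

Given a protein expression matrix, an optional PTM matrix (site keys like
`MAPK1:Y187:phosphorylation`), a two-cluster sample design and a reference
bundle (ligand–receptor pairs, pathway memberships, a partially directed
intracellular network, and a PTM–pathway reference), the pipeline:

1. enumerates candidate (ligand, receptor, pathway) triples, with targets
   derived by pathway-restricted network traversal from the receptor;
2. scores each triple on expression statistics (two-sided Wilcoxon by
   default, pluggable) under sign constraints — ligand up-regulated,
   receptor sign configurable — with a pathway p-value from an
   order-statistic rank statistic of the sorted target p-values,
   Monte-Carlo calibrated; the overall p-value is the product of the
   ligand, receptor and pathway p-values;
3. refines each triple with PTM events: reference records of the pathway
   whose substrate (and enzyme, when annotated) are detected and whose
   site carries a differential result, flagged for direction-aware
   concordance (discordant events are kept, not discarded);
4. computes a pathway-level PTM p-value by the same rank statistic,
   applies Benjamini–Hochberg within the expression and PTM p-value
   families, and selects triples by dual thresholds (expression-only, or
   PTM-rescued at a relaxed expression threshold) or by a p-value product.

PTM matrices are normalized by the parent protein (ratio or, for
log-scale data, difference). A global protein mode can replace all site
statistics of a protein by its most extreme site. Two dedicated analyses
are included: cross-PTM-type crosstalk between two runs, and
PhosphoSitePlus flat-file annotation of events. A synthetic-data module
generates bundles and matrices with planted, seed-deterministic signal
for end-to-end testing, plus recovery scoring.

## CLI

```sh
ptmlri simulate --out run/ --seed 1 --n-planted 1       # synthetic run directory
ptmlri build-ptmdb reactions.json --out ptm_reference.tsv [--split-by-type]
ptmlri infer --expr run/expr_matrix.tsv --ptm run/ptm_matrix.tsv \
    --design run/design.tsv --bundle-dir run/bundle \
    --config config.yaml --out-dir results_a/
ptmlri crosstalk results_a/ results_b/ --out-prefix crosstalk
ptmlri annotate-psp --events results_a/events.tsv \
    --regulatory Regulatory_sites.gz --kinase-substrate Kinase_Substrate_Dataset.gz \
    --out annotated.tsv
ptmlri export-cytoscape results_a/ --out-prefix network
ptmlri export-comparison results_a/ --out comparison.tsv
```

`config.yaml` may set any `InferenceConfig` field (unknown keys are
rejected), e.g. `ptm_norm_mode: difference`, `alpha_expr_relaxed: 0.25`,
`seed: 1`. Every run writes a config echo and run metadata for exact
reproduction. All inputs and outputs are plain TSV/JSON/YAML/SIF;
PhosphoSitePlus files may be gzip-compressed.

Simulated matrices are log-scale, so pair them with
`ptm_norm_mode: difference` (the default `ratio` matches intensity-scale
data divided by parent protein abundance).

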