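# immunoclone

Single-cell immune repertoire analytics for paired GEX + VDJ data:

- **vdj** — AIRR / 10x contig parsing, per-droplet chain selection by UMI
  support, SHM quantification from V-identity, isotype usage tables.
- **clones** — B-cell clone calling as connected components of the union of
  a CDR3 point-mutation network (Hamming distance 1) and identical
  CDR3 + V/J-family identity; T-cell clones on TRB (± TRA) identity.
- **clonality** — depth-normalised clonal expansion: intra-subset (% of
  cells in clones with ≥2 sampled members at depth 5) and inter-subset
  (% in clones with ≥3 sampled members lineage-wide at depth 50), both as
  means over many seeded subsamples; per-sample repertoire feature matrices.
- **transitions** — clonal-overlap matrices between phenotypes,
  recirculating / blood-only / tumour-only clone classification, migration
  linkage between blood and tumour phenotypes, known-TCR screening.
- **interactions** — cell-count-independent receptor-ligand scoring
  (product of expressing fractions per patient, subsets with ≥3 cells),
  link counts, ranked receptor views, multivariate edge comparisons.
- **scoring** — binned-control signature scores, logistic threshold
  learning (pAPC classification and pool composition), declarative YAML
  threshold gating, per-sample gene-correlation modules (Fisher-z averaged,
  complete linkage), and repeated class-balanced SVM label transfer.
- **stats** — one-way MANOVA (Pillai's trace) and composition tables.
- **synthetic** — seeded generators for contig tables, metadata, count
  matrices and known-TCR references with controllable clonal structure;
  every module is testable offline against generator ground truth.

## CLI

```bash
immunoclone simulate --config cfg.yaml --out data/
immunoclone assign-chains --in data/contigs.tsv --dialect airr --out chains.tsv
immunoclone call-clones --chains chains.tsv --receptor bcr --out clones.tsv
immunoclone clonality --clones clones.tsv --meta data/meta.tsv \
    --metric intra --depth 5 --reps 1000 --seed 7 --out clonality.tsv
immunoclone transitions --clones clones.tsv --meta data/meta.tsv --out overlap.tsv
immunoclone interactions --matrix data/expression --meta data/meta.tsv \
    --min-cells 3 --out interactions.tsv
immunoclone run --config run.yaml --out results/run1   # full pipeline
immunoclone validate --config run.yaml
```

A full-pipeline YAML config needs a `seed` and either a `simulate:` section
(SimConfig fields) or an `inputs:` section (`contigs`, `meta`, `dialect`);
optional `clonality:` (`intra_depth`, `inter_depth`, `reps`) and
`interactions:` (`min_cells`, `pairs`, `include_self`) blocks tune the
stages. A bundled 2,000-cell example lives at
`src/immunoclone/data/fixture_config.yaml`. Outputs carry a provenance
header (tool version, config hash, seed) and reruns are byte-identical.

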