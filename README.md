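# mutsig96

Somatic mutational-signature analysis on the 96-category pyrimidine-collapsed
trinucleotide scheme:

- **catalog** — parse somatic SNVs (MAF-lite TSV or VCF), extract trinucleotide
  context from a reference FASTA, collapse to the pyrimidine strand, and build
  96 × N mutation catalogs; stratify X(C>T)G mutations by CpG-island membership
  (BED intervals).
- **nmf** — factorize catalogs by multiplicative-update NMF under the
  generalized Kullback–Leibler divergence, with per-sample multinomial
  bootstrapping, cosine k-medoids consensus clustering of replicate signatures,
  silhouette stability, and cophenetic/sparseness-based rank selection.
- **annotate** — match extracted signatures against a library of named
  archetypes (S, UVA, UVB, K, L, H, nonCGI, flat) by optimal-assignment cosine
  similarity; build cohort signature profiles; detect samples dominating a
  signature's exposure.
- **association** — Welch t-tests of signature loads between covariate groups,
  median-split load-vs-covariate tests, load–expression correlations, and
  expression-ordered summaries.
- **synthetic** — fully seeded generators for archetype signatures, log-normal
  burdens × Dirichlet mixture exposures, multinomial/Poisson catalogs,
  synthetic genomes with CpG-island tracks on which every catalog count is
  realized as a placeable mutation (exact round trip), and clinical covariates
  with planted effects.
- **workflow / cli** — end-to-end runs (simulate → catalog → extract →
  annotate), the non-CGI ablation, and the outlier-sample ablation, driven by
  a YAML config and a single master seed.

## CLI

```sh
mutsig96 extract --config run.yaml --out runs/demo
mutsig96 catalog --mutations muts.tsv --genome ref.fa --out catalog.tsv
mutsig96 ablate-noncgi --config run.yaml --out runs/ncgi
mutsig96 ablate-outlier --config run.yaml --out runs/outlier
mutsig96 simulate --config run.yaml --out runs/sim
mutsig96 all --config run.yaml --out runs/all
```

A minimal simulation config:

```yaml
simulation:
  n_samples: 120
  signature_names: [S, K, nonCGI, flat]
  burden_median: 300.0
  burden_sigma: 1.0
rank_range: [3, 4, 5, 6, 7]
n_bootstrap: 10
n_restarts: 20
seed: 7
```

For real data replace `simulation:` with

```yaml
inputs:
  mutations: cohort.maf.tsv   # or .vcf (format: vcf)
  genome: reference.fa
  cgi_bed: cpg_islands.bed    # optional
  covariates: clinical.tsv    # optional
```

Exit codes: 0 success, 2 validation error, 3 data-integrity error,
4 insufficient data.

## Conventions

- Category order: substitutions C>A, C>G, C>T, T>A, T>C, T>G; within each,
  5' base then 3' base, both A/C/G/T. Labels look like `A(C>T)G`.
- Mutation records are 1-based (MAF/VCF); interval tracks are 0-based
  half-open (BED); CGI membership is tested at the mutated base.
- All TSV floats are written at 6 significant digits; every run directory
  contains a manifest with the config hash and derived stage seeds.
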