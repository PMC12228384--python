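# roiflow

Analysis pipeline for ROI-level spatial transcriptomics count data from a
two-arm study (PD vs control slides, myenteric-plexus and epithelium
compartments). The stages, run independently per compartment:

1. **synth** — synthetic study designs, negative-binomial count matrices
   with planted group effects, slide-level batch factors and area-driven
   library sizes; scale-free PPI networks; gene-set libraries with planted
   enriched terms. Everything downstream is testable without any download.
2. **normalize** — between-sample signal-intensity normalization
   (upper-quartile / full-quantile / median) followed by replicate-based
   estimation of unwanted variation (within-group centering + SVD) that is
   either regressed out of the matrix or passed on as design covariates.
3. **diffexp** — NB Wald differential expression: median-of-ratios size
   factors, method-of-moments dispersions shrunk toward a 1/mu trend,
   per-gene IRLS, Benjamini-Hochberg adjustment, and the DEG filter
   (adjusted p < 0.05 and |log2FC| > 0.5).
4. **enrich** — gene-set over-representation: hypergeometric upper-tail p,
   BH adjustment, contingency odds ratio, and combined score
   `OR x (-ln p)` against a GMT library (default background 20,003 genes).
5. **netprop** — fold-change-seeded random walk with restart
   (`p(t+1) = (1-r) W' p(t) + r p0`, column-normalized adjacency W',
   default r = 0.5) plus ordered-pair betweenness centrality; key genes are
   the top-20 by propagation probability that also contribute to a
   significant pathway.
6. **pipeline** — one TOML config, deterministic end to end, TSV/JSON
   outputs and a structured run report.

## CLI

```sh
# a small self-consistent demo study (counts, metadata, GMT, network, truth)
roiflow simulate --outdir demo-data --seed 3 --demo

# full-scale synthetic study (18,677 genes x 120 ROIs)
roiflow simulate --outdir data --seed 1

# whole pipeline from a config file
cat > run.toml <<EOF
counts = "demo-data/counts.tsv"
metadata = "demo-data/metadata.tsv"
gmt = "demo-data/genesets.gmt"
network = "demo-data/network.tsv"
outdir = "out"
background_size = 1500
compartments = ["plexus", "epithelium"]
EOF
roiflow run-all --config run.toml

# individual stages
roiflow normalize --counts data/counts.tsv --metadata data/metadata.tsv --outdir norm
roiflow diffexp --counts norm/normalized_counts.tsv --metadata data/metadata.tsv \
    --covariates norm/unwanted_factors.tsv --out deg.tsv
roiflow enrich --genes up_genes.txt --gmt sets.gmt --out enrichment.tsv
roiflow netprop --deg-table deg.tsv --network ppi.tsv --outdir net \
    --restart-rate 0.5 --top-n 20
```

File formats: counts as genes x ROIs TSV (first column the gene id),
metadata TSV keyed by `roi_id`, gene sets as GMT, networks as 2-column
edge-list TSV or BioGRID TAB3 (`Official Symbol Interactor A`/`B`).

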