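# ctap

Cell-type abundance phenotyping (CTAP) for multi-sample single-cell cohorts:
stratify samples by the composition of the six canonical major cell types
(T, B/plasma, NK, myeloid, stromal, endothelial), associate single-cell
neighbourhoods with the resulting phenotypes, transfer phenotype labels to
flow-cytometry compositions and bulk RNA-seq, and run the downstream
association statistics. A bundled synthetic-cohort generator makes the whole
pipeline testable with no external data.

## Modules

| module | purpose |
| --- | --- |
| `ctap.simulate` | synthetic cohorts: Dirichlet compositions over 6 latent phenotypes, within-type state mixtures, NB counts with planted marker/cytokine/risk genes, Gaussian embeddings, pseudobulk and flow derivatives |
| `ctap.stratify` | per-sample compositions, Ward/Euclidean clustering with bootstrap-ARI stability model selection, enrichment-z naming, centroid projection, composition PCA, cytokine-pseudobulk categorization |
| `ctap.neighbourhood` | kNN graph, diffusion neighbourhood abundance matrix (NAM), covariate-adjusted min-p permutation association, per-cell empirical-null FDR masks, per-state summaries |
| `ctap.classify` | flow nearest-neighbour label transfer (with leave-one-out accuracy), signature derivation + NNLS bulk deconvolution and classification, longitudinal transition summaries |
| `ctap.downstream` | ANOVA-style variance explained, proportion correlations, low-count gene filter, expression-matched risk-gene permutation tests, enrichment counts, logistic response odds ratios, paired-biopsy stability test |
| `ctap.io` / `ctap.validate` / `ctap.cli` / `ctap.pipeline` | plain-text cohort layout (MTX + TSVs), input validation with canonical-name suggestions, manifest checks, CLI, end-to-end pipeline runner |

## CLI

```sh
ctap simulate --out cohort/ --seed 1 --n-samples 60
ctap stratify --cells cohort/cells.tsv --k-range 2:8 --boot 200 --seed 1 --out strat/
ctap associate --cohort cohort/ --labels strat/ctap_labels.tsv \
    --celltype T --phenotype TB --covars age,sex,log_n_cells \
    --perm 1000 --seed 1 --out assoc/
ctap classify-flow --train comp.tsv --train-labels strat/ctap_labels.tsv \
    --test flow.tsv --out flow_labels.tsv
ctap classify-bulk --bulk bulk.tsv --cohort cohort/ \
    --model strat/ctap_model.json --out bulk_labels.tsv
ctap transitions --pairs pairs.tsv --out transitions.json
ctap downstream --analysis variance --samples cohort/samples.tsv \
    --labels strat/ctap_labels.tsv --seed 1 --out variance.json
ctap validate mtx=cohort/matrix.mtx genes=cohort/genes.tsv barcodes=cohort/barcodes.tsv
ctap pipeline --out run/ --seed 1     # simulate -> ... -> downstream + manifest
```

Composition inputs are samples x cell-type TSVs whose rows sum to 1; cohort
directories hold a MatrixMarket counts matrix plus gene/barcode/cell/sample
TSVs (see `ctap.io` for the exact layout).

## Notes

- The neighbourhood association test is a self-contained, documented variant
  of covarying-neighbourhood analysis (union-symmetrized kNN, 3 diffusion
  steps, Westfall-Young min-p over NAM principal components, two-sided
  empirical-null FDR); it does not reproduce any package's exact defaults.
- The bulk classifier is a transparent realization (per-type CPM signature
  profiles, NNLS on marker genes, nearest-centroid assignment); published
  implementations may differ.
- The default simulation preset ships six phenotypes named EFM/F/TF/TB/TM/M
  with illustrative composition means chosen so the naming rule recovers
  those names; they are package defaults, not measured values.
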