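# cernakit

Competing-endogenous-RNA (ceRNA) network inference and incremental
biomarker evaluation for matched case–control studies, with a
synthetic-study generator that makes the whole pipeline verifiable
against known ground truth.

Circular RNAs (circRNAs) can act as miRNA sponges: by sequestering a
shared miRNA they de-repress that miRNA's target genes, so a circRNA
acting through the ceRNA mechanism should move in the same direction as
the genes it protects. `cernakit` turns that hypothesis into a tested
pipeline for coronary heart disease (CHD) biomarker discovery:

- **screen** — quantile normalisation, ComBat batch adjustment, and a
  fold-change + *t*-test differential-expression screen
  (|FC| ≥ 1.5 for the circRNA array, |FC| ≥ 1.2 for merged gene
  cohorts, p < 0.05), intersected with an immune-gene list;
- **network** — join circRNA–miRNA and miRNA–gene interaction tables on
  shared miRNAs, prune direction-inconsistent circ–miR–gene paths, score
  a PPI graph (combined score > 0.4) by betweenness, closeness and
  degree, select hub genes strictly above all three averages, and
  extract the circRNA–miRNA–hub-gene sub-network;
- **cohort** — matched case–control statistics (Pearson χ² without
  continuity correction, Mann–Whitney with tie-corrected Z, pooled *t*,
  Spearman, 2^−ΔΔCt, greedy sex/age ± 3-year matching, the
  discordant-pair sample-size formula) and unconditional logistic
  regression with Wald CIs;
- **evaluate** — AUC via the Mann–Whitney estimator with DeLong
  variances, the DeLong test for correlated AUCs, the integrated
  discrimination improvement (IDI) and the category-free net
  reclassification improvement (NRI) of markers added to a clinical
  risk model (smoking, drinking, hypertension, diabetes).

A `StudyBlueprint` describes an entire synthetic study — planted
differential features, the intended tripartite network, PPI wiring,
covariate prevalences, marker odds ratios — and the generators in
`cernakit.simulate` emit every input the pipeline consumes, so each
stage can be checked end to end. See `docs/methods.md` for models,
conventions and limitations.

## Worked example

```python
from cernakit import RunConfig, run_pipeline, paper_scale_blueprint

summary = run_pipeline(RunConfig(blueprint=paper_scale_blueprint(seed=1),
                                 outdir="cerna_run"))
print(summary["n_de_circ"], summary["n_de_circ_up"], summary["n_de_circ_down"])
print(summary["cerna"])
print(summary["hub_genes"])
print(summary["subnetwork"])
```

prints

```
22 21 1
{'n_circ': 14, 'n_mir': 24, 'n_gene': 15, 'n_nodes': 53, 'n_edges': 56}
['gene_0001', 'gene_0004', 'gene_0003', 'gene_0002']
{'n_circ': 5, 'n_mir': 6, 'n_gene': 4, 'n_nodes': 15, 'n_edges': 17}
```

— the screen recovers the 22 planted differential circRNAs (21 up, 1
down), the joined-and-pruned ceRNA network has exactly the designed
53-node/56-edge composition (14 circRNAs, 24 miRNAs, 15 immune genes),
four genes exceed the PPI network averages on betweenness, closeness and
degree simultaneously, and their sub-network nominates 5 circRNAs through
6 miRNAs. On the simulated 100 vs 100 matched cohort,
`model_comparison.tsv` in the output directory then reports, for
example, AUC 0.713 for the clinical model rising to 0.758 with the first
informative marker (IDI 0.051, NRI 0.34): positive reclassification
gains of the size expected for a marker with an odds ratio near 1.5 per
SD of log2 expression.

The same stages are exposed on the command line:

```
cerna simulate --outdir run --seed 1
cerna de --matrix run/circ_matrix.tsv --meta run/circ_meta.tsv --fc 1.5 --out run/circ_de.tsv
cerna network --circ-mir run/circ_mir.tsv --mir-gene run/mir_gene.tsv \
      --circ-de run/circ_de.tsv --gene-de run/gene_de.tsv --ppi run/ppi.tsv --outdir run/net
cerna stats --cohort run/cohort.csv --out run/table2.tsv
cerna evaluate --cohort run/cohort.csv --markers circ_0001,circ_0003 --out run/table4.tsv
cerna run --seed 1 --outdir run_all
```

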