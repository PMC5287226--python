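# shapegene

Couple quantitative cell-morphology summaries to transcription and clinical
outcome. The pipeline links per-cell-line shape statistics to gene
expression, assembles a shape-gene interaction network, classifies network
genes as regulators or effectors of selected transcription factors from a
gene-knockdown expression panel, fits "metagene" regression models by
forward selection, and associates metagene scores with tumor grade and
survival. A synthetic-data generator with planted ground truth exercises
every stage without external downloads.

## Stages

| stage | module | what it does |
|---|---|---|
| simulate | `shapegene.synthdata` | generate all five input kinds + planted truth |
| correlate | `shapegene.morphology` | per-line feature means/SDs; Spearman screen with BH (or Storey) FDR |
| network | `shapegene.netbuild` | correlation + interaction edges; degree / closeness / stress / betweenness |
| paths | `shapegene.netbuild` | optimal + suboptimal feature-to-TF paths (other features/TFs excluded); subnetwork |
| rnai | `shapegene.rnai` | knockdown panel consolidation; expression/activation regulator and effector calls (hypergeometric overlap, sign concordance) |
| subtypes | `shapegene.subtypes` | complete-linkage clustering of lines; differential networks |
| metagene | `shapegene.metagene` | forward-selection OLS metagenes + random-metagene control |
| clinical | `shapegene.clinical` | Jonckheere–Terpstra grade trend, quantile-grid dichotomization, Kaplan–Meier/log-rank, univariate + multivariate Cox |

All thresholds live in `shapegene.config.PipelineConfig` (plain-text
`key = value` config files; defaults follow the published analysis:
SD cutoff 0.3, |rho| > 0.7, interaction score ≥ 0.4, knockdown validity
z < −0.4, |z| > 1.5 significance, 10% target coverage, hypergeometric
alpha 0.05, z-difference 0.5, expression floor 7.0, R² stop 0.9, 4–10 genes
per metagene, dichotomization quantiles 0.2–0.8).

## CLI

Stages run over a shared output directory and hand off through files; a
`manifest.json` records the config hash, seed, checksums and row counts of
every artifact, and is byte-identical across reruns with the same seed.

```sh
# full pipeline on synthetic data
shapegene --out runs/demo --seed 3 all

# or stage by stage (missing predecessors produce an actionable error)
shapegene --out runs/demo --seed 3 simulate
shapegene --out runs/demo --seed 3 correlate
shapegene --out runs/demo --seed 3 network
shapegene --out runs/demo --seed 3 paths --tf SMAD3 --tf RELA
shapegene --out runs/demo --seed 3 rnai
shapegene --out runs/demo --seed 3 subtypes
shapegene --out runs/demo --seed 3 metagene
shapegene --out runs/demo --seed 3 clinical

# custom thresholds
shapegene --config my.cfg --out runs/custom all
```

Outputs are plain text: TSV/CSV tables, GraphML/SIF networks, Newick
dendrograms, JSON models and manifests.

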