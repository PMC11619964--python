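# moals

Multi-omics modelling for ALS-style cohorts: pathway-level gene selection
from expression profiles, rare-variant gene burdens, and a multi-task
variational-autoencoder model that jointly predicts disease status,
age at first symptoms, and survival.

## Who this is for

Researchers working with paired transcriptome + genome data on an
imbalanced case/control cohort (the motivating setting is ~600 ALS cases
against ~80 controls) who want a single latent representation of both
omics layers feeding three clinical endpoints at once, plus a fully
synthetic cohort generator for method development when the real data are
access-restricted.

## The method

1. **Pathway gene selection.** Genes are soft-clustered on their
   standardized expression profiles by fuzzy k-means,

       u_ij = 1 / Σ_k (‖x_i − v_j‖/‖x_i − v_k‖)^(2/(m−1)),

   clusters are tested for pathway enrichment (one-sided hypergeometric,
   BH-adjusted across all cluster × set tests), and every gene in a
   cluster enriched for a target pathway (FDR < 0.05) is kept.
2. **Variant prioritization.** VEP-annotated variants are filtered to
   canonical-transcript, gene-anchored records with population allele
   frequency < 0.01 or absent; consequences are scored in tiers
   (frameshift / stop-gained / transcript-ablation → 5, stop-lost /
   start-lost / transcript-amplification → 3, splice donor/acceptor → 2)
   and aggregated per sample and gene into a score-weighted allele-count
   burden matrix.
3. **Deep embedding + heads.** Both blocks, min-max scaled to [0,1], are
   concatenated and encoded by a VAE (z = μ + σ⊙ε; closed-form Gaussian
   KL; per-block binary cross-entropy reconstruction). Heads on the
   latent mean handle classification (cross-entropy), onset-age
   regression (MSE), and discrete-time survival via multi-task logistic
   regression (MTLR): interval scores y′ define a softmax over monotone
   survival-status vectors, giving survival curves S(t_i) and a
   discrete-hazard risk score r = Σ_i h(t_i).
4. **Three-stage training with GradNorm.** Unsupervised embedding first,
   then heads with the embedding frozen, then joint fine-tuning where
   GradNorm re-balances task weights from gradient norms at the last
   encoding layer. The networks are implemented in numpy with
   hand-written backward passes, verified against finite differences.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
import moals
from moals.evaluation import cross_validate

cfg = moals.SimulationConfig(n_samples=200, n_cases=150, n_controls=50,
                             n_genes_expression=120, n_genes_burden=30,
                             n_burden_signal_genes=15, seed=2)
cohort = moals.generate_cohort(cfg)

selected, enrichment, clustering = moals.select_genes(
    cohort.expression, moals.synthetic_data.truth_gmt(cohort),
    target_set_names=["BLOCK0", "BLOCK1"], n_clusters=6, seed=0)
print(f"selected {len(selected)} of {len(cohort.expression.features)} genes")

expr = cohort.expression.subset_features(selected)
report = cross_validate([expr, cohort.burden], cohort.samples, k=5, seed=0,
                        model_kwargs=dict(latent_dim=16, hidden_dims=(64, 32),
                                          head_hidden=(16,), m_intervals=8))
for key in ("accuracy", "auc", "r2", "c_index", "ibs"):
    m = report["pooled"][key]
    print(f"{key:8s} {m['mean']:.3f}  (95% CI {m['ci_low']:.3f}-{m['ci_high']:.3f})")
```

prints

```
selected 60 of 120 genes
accuracy 0.890  (95% CI 0.819-0.961)
auc      0.933  (95% CI 0.871-0.995)
r2       0.291  (95% CI -0.029-0.612)
c_index  0.768  (95% CI 0.700-0.837)
ibs      0.116  (95% CI 0.085-0.147)
```

The selection step recovers exactly the two planted co-expression blocks
(60 of 120 genes) that carry the disease and onset factors. On this small
cohort the classifier and survival head comfortably beat chance (majority
rate 0.75, C = 0.5 for random risks); the onset regression is noisier at
n = 200, as the wide fold CI shows.

The same flow is available from the shell:

```sh
moals simulate --config cohort.yaml --out data/
moals select-genes --expr data/expression.tsv --gmt data/truth_blocks.gmt \
      --clusters 8 --target-sets BLOCK0,BLOCK1 --out genes.txt
moals prioritize-variants --vcf cohort.vcf --samples data/samples.tsv \
      --out burden.tsv
moals train --expr data/expression.tsv --burden data/burden.tsv \
      --samples data/samples.tsv --out run/
moals evaluate --expr data/expression.tsv --burden data/burden.tsv \
      --samples data/samples.tsv --folds 5 --out report/
```

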