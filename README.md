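# cazlearn

Annotating carbohydrate-active enzymes (CAZymes) from protein-language-model
embeddings.

Most unannotated microbial proteins resist homology-based annotation: BLAST-
and HMM-style tools miss remote homologs whose conservation is structural
rather than sequence-level. CAZymes — glycoside hydrolases (GH),
glycosyltransferases (GT), carbohydrate esterases (CE) and polysaccharide
lyases (PL), organised into numbered families and subfamilies such as
`GH43_18` — are a prime example: families share fold and mechanism even when
pairwise sequence identity is low. `cazlearn` classifies proteins from
fixed-length embedding vectors produced by a protein language model (pLM),
so the decision rides on the pLM's contextual representation rather than on
alignable sequence similarity.

The package is for computational microbiome researchers who have (or can
generate) per-protein embeddings for a gene catalog and want CAZyme calls,
benchmarks against score files from other annotators, interpretability
probes, and a disease differential-abundance analysis over the annotated
catalog.

## The method

**Two-stage classification.** For a query embedding x ∈ R^D (D = 1024 for
the reference pLM):

1. *Gate*: a random forest (200 trees, fixed random state) scores
   P(CAZyme | x) as the fraction of trees voting CAZyme; queries with score
   ≥ τ (default 0.5) pass.
2. *Family assignment*: a feedforward network
   `D → 256 → 512 → K` (ReLU, softmax) maps the embedding to a distribution
   over the K family/subfamily labels present in the training ontology.

**Imbalance-weighted training.** Family sizes are wildly skewed (CEs are
~4 % of catalogued sequences), so the network minimises a weighted
cross-entropy with per-class weight w_c ∝ 1/n_c (inverse of the training
count, normalised to mean 1): mislabelling a rare family costs more than
mislabelling an abundant one. Hyperparameters (hidden sizes, batch size,
learning rate) are chosen by random search (20 candidates, 100-epoch
budget) under a successive-halving schedule that prunes the worst half of
the pool, by validation loss, at geometrically spaced rungs.

**Training-set curation.** Positive (CAZyme) sets are length-filtered
(> 5,000 aa removed), deduplicated at 100 % identity, and clustered at 60 %
identity (greedy longest-first, CD-HIT-style) so no two representatives
exceed the threshold; negative sets are purged of anything registering a
homology hit against the positives.

**Downstream analyses.**

- *Benchmarking*: precision / recall / F1, K×K confusion with
  micro-averaged accuracy, and ROC / precision-recall curves built from any
  score file (forest votes, or third-party e-values via a polarity flag).
- *Latent probes*: exact Euclidean nearest-neighbor search against a
  reference embedding database, and a sliding-window in-silico mutagenesis
  probe that substitutes each 10-residue window with its most distant
  BLOSUM62 replacements, re-embeds, and tracks the probability of a target
  family — localising which sequence segments the classification depends on.
- *Differential abundance*: gene × sample counts are prevalence-filtered
  (< 10 % dropped), zero-imputed (half the per-gene minimum nonzero),
  log2-transformed and z-scored per gene, and regressed (OLS) on a disease
  indicator plus covariates; Benjamini–Hochberg correction at q ≤ 0.25,
  volcano-plot label rules, and a CAZyme prioritization score — the mean of
  a gene's logFC percentile and its family-probability.

A deterministic synthetic-fixture module generates every input the pipeline
consumes: Gaussian embedding clusters with controlled separation, random
proteins with planted homologous segments and motifs, and negative-binomial
count matrices with planted effects and truth tables.

## Worked example

Train both stages on a synthetic world of 5 CAZyme families plus a
non-CAZyme cloud, then annotate held-out proteins:

```python
import numpy as np
import cazlearn as cz

fx = cz.simulate_embeddings(6, [80]*5 + [400], dim=32, separation=6.0, seed=7)
neg = cz.FamilyLabel("GH", 6)           # the 6th cloud plays the non-CAZymes
tr, trl, te, tel = fx.split(0.25, seed=7)

gate = cz.train_gate(
    tr.subset([i for i in tr.ids if trl[i] != neg]),
    tr.subset([i for i in tr.ids if trl[i] == neg]),
    seed=0,
)
spec = cz.SearchSpec(n_candidates=4, max_epochs=20, grace_period=5,
                     hidden_range=(32, 128), batch_range=(32, 128))
val_ids = [i for i in te.ids if tel[i] != neg]
fam, report = cz.train_family(
    tr.subset([i for i in tr.ids if trl[i] != neg]),
    trl, te.subset(val_ids), tel, spec=spec, seed=1,
)
preds = cz.annotate(te, gate, fam)

gate_acc = np.mean([p.is_cazyme == (tel[p.id] != neg) for p in preds])
called = [p for p in preds if p.is_cazyme and tel[p.id] != neg]
fam_acc = np.mean([p.family == tel[p.id] for p in called])
print(f"gate accuracy      {gate_acc:.3f}  ({len(preds)} held-out proteins)")
print(f"family accuracy    {fam_acc:.3f}  ({len(called)} gate-positive CAZymes)")
```

which prints

```
gate accuracy      0.995  (200 held-out proteins)
family accuracy    0.990  (100 gate-positive CAZymes)
```

i.e. 199 of the 200 held-out proteins are gated correctly, and 99 of the
100 true CAZymes that passed the gate receive their planted family. Each
`PredictionRecord` carries the gate score, the family label and its
probability — e.g. `p01_0004 gate=0.96 GH1 p=1.00` — and the same columns
are written by the `cazlearn annotate` CLI as a versioned TSV.

The CLI mirrors the library: `cazlearn curate | embed | train-gate |
train-family | annotate | neighbors | probe | diffabund | simulate`
(see `cazlearn --help`).

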