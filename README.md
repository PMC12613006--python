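# fewdrp

Few-shot drug-response prediction for cancer cell-line screens, with
pathway-level interpretability, and a fully ground-truthed synthetic screen
generator for testing every component without external data.

## The problem

Drug-sensitivity screens (LN_IC50 per cell line × drug) are sparse and
heterogeneous: most (drug, tissue) contexts have few labelled samples, and
response distributions shift across tissues. `fewdrp` treats each
drug–tissue pair as a *task* and trains a single model that adapts to a new
task from a handful of examples:

- **Cell-line branch** — multi-omics profiles (expression, CNV, methylation,
  CRISPR effect) with missing values imputed by clamped feature propagation
  over a gene–gene network (`x ← D^{-1/2} A D^{-1/2} x`, observed entries
  clamped, 40 iterations); a 3-layer residual GCN; a pathway-masked sparse
  linear layer (one unit per pathway sees only its member genes); pathway
  self-attention → one token per pathway, `Z^c ∈ R^{P×n_e}`.
- **Drug branch** — SMILES → OGB-style molecular graph; a slim graph
  transformer with centrality, shortest-path (spatial) and bond (edge)
  attention biases and a global readout token → `z^d ∈ R^{n_e}`; pretrained
  on lipophilicity (Crippen logP) with a warmup/cosine schedule.
- **Predictor** — tokens `H = concat(Z^c, z^d) ∈ R^{(P+1)×n_e}` fused by
  multi-head cross-attention, then two feed-forward networks → scalar
  LN_IC50.
- **Meta-learning (MAML)** — inner loop: a few SGD steps on a task's
  10-sample support MAE; outer loop: Adam on the post-adaptation 20-sample
  query MAE across tasks. Second-order meta-gradients are exact (the numpy
  autodiff core supports gradients of gradients); a first-order switch is
  provided. k-shot prediction fine-tunes on k records and predicts the rest
  (k = 0 uses the meta-parameters unchanged).
- **Explainer** — drug→pathway cross-attention row (averaged over repeated
  support-resampled fine-tunes, most-confident head) ranks pathways; the
  absolute sparse-layer weights rank genes within each pathway;
  feature-zeroing measures per-channel omics importance.
- **Evaluation & statistics** — MSE/MAE/PCC/SCC at pooled / drug / tissue /
  drug–tissue levels with 95% CIs; responder (RECIST) discrimination via
  Mann–Whitney AUC; response-distribution statistics (STD, bimodality
  coefficient, density coverage); LAD median regression of task SCC on
  mechanism/tissue indicators with permutation + BH-FDR inference and
  bootstrap CIs.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Simulate a small screen, pretrain the drug encoder, meta-train, predict and
evaluate — all from the shell:

```bash
fewdrp simulate --out work --seed 5 --config fix.yaml
# wrote 372 responses over 12 tasks to work

fewdrp pretrain-drug --smiles work/drugs.csv --labels work/logp.csv \
       --out drug.npz --epochs 3 --warmup-epochs 1
# pretraining loss 8.9301 -> 1.8926 (drug.npz)

fewdrp meta-train --workdir work --out meta.npz --meta-config meta.yaml \
       --drug-ckpt drug.npz --seed 1
# meta-trained 2 epochs; best val SCC^dt 0.232

fewdrp predict --workdir work --ckpt meta.npz --k 5 --out preds.csv \
       --meta-config meta.yaml --seed 2
fewdrp evaluate --predictions preds.csv --out metrics.csv
# SCC^dt 0.162 (95% CI 0.017..0.307)

fewdrp explain --workdir work --ckpt meta.npz --drug D004 --tissue tissue0 \
       --sample S0000 --annotations work/ground_truth.json --repeats 2 \
       --out expl.json --meta-config meta.yaml
# top pathway: PW001 (attention 0.027)
```

The numbers above come from a deliberately tiny 2-epoch demo configuration
(60 genes, 6 pathways, 6 drugs): `SCC^dt 0.162` is the mean Spearman
correlation between predicted and measured LN_IC50 per drug–tissue pair —
near zero, as expected after 2 epochs; the `explain` output is the
attention weight the drug token pays to its top-ranked pathway. The
benchmark-scale runs (40–70 epochs) live in `fewdrp.studies` and reach
10-shot SCC ≈ 0.35 on unseen-drug meta-test tasks, versus ≈ 0.23 for the
conventionally trained ablation.

Library use mirrors the CLI:

```python
from fewdrp import make_fixture, DrugResponseModel, ModelConfig, MetaConfig
from fewdrp.meta_learning import meta_train, k_shot_finetune
from fewdrp.task_builder import holdout_unseen_drugs, split_train_val

fx = make_fixture()                       # default synthetic screen
model = DrugResponseModel(fx.dataset.network, fx.dataset.pathways,
                          ModelConfig.desk())
rest, unseen = holdout_unseen_drugs(fx.tasks, seed=0)
train, val = split_train_val(rest, seed=0)
params, log = meta_train(model, fx.dataset, train, val,
                         MetaConfig(second_order=False, epochs=10), seed=0)
adapted, preds = k_shot_finetune(model, params, fx.dataset, unseen[0],
                                 k=10, config=MetaConfig(), seed=0)
```

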