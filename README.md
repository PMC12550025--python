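# catgen

Reaction-conditioned catalyst generation and performance prediction with a
conditional variational autoencoder (CVAE), plus validity-correcting
molecular reconstruction, reaction-data curation, generation metrics and
latent-space Bayesian optimization for inverse catalyst design.

**Who it is for.** Computational chemists and ML practitioners who want to
(i) learn a generative latent space of homogeneous catalysts (including
multi-fragment organometallic complexes) conditioned on the reaction they
are used in, (ii) predict catalytic performance (percent yield, binding
energy, ΔΔG‡) jointly with generation, and (iii) search that latent space
for catalysts predicted to hit a target performance under fixed reaction
conditions.

## The model

A catalyst is encoded as a one-hot matrix triple **M** = (*T*, *A*, *B*):
*T* ∈ {0,1}^S marks the molecule size, *A* ∈ {0,1}^(S×At) the atom type
per node, *B* ∈ {0,1}^(S×S×Bt) the bond type per node pair. At the
default sizing (S=100, At=68 atom channels, Bt=6 bond channels) the
flattened representation has 100 + 100·68 + 100·100·6 = **66 900**
entries. The reaction context — graph-attention embeddings of reactants,
reagents (or a learned no-reagent token) and product, the log reaction
time and a molecular-weight cluster one-hot — forms a condition vector
**c**. An encoder Q(**z**|**x**, **c**) maps the catalyst embedding to a
D-dimensional Gaussian latent; a three-stage sequential decoder
P(**M**|**z**, **c**) (length → annotation → bilinear/outer-product
adjacency, teacher-forced at ratio 0.25 during training) reconstructs the
matrix; a predictor f(**z**, **c**) estimates the target from the mean
latent. Training minimizes

    L_total = α·L_recons + β·L_KL + L_prediction

Decoded logits become molecules through a rule-based correction: bonds
are assigned in descending probability order with valence checking after
each addition (formal charges are added where that legalizes a bond,
never on carbon), followed by aromatic clearance, sanitization and
removal of unconnected carbon atoms. Generated sets are scored with
Valid / Valid(Task) / Unique / Novel / IntDiv / SNN over ECFP4 (2048-bit)
Tanimoto similarity, and inverse design runs Gaussian-process Bayesian
optimization of a penalized decode→re-embed→re-encode→predict objective
inside the integer bounding box of the training latents (or a ball
around an anchor catalyst).

See `docs/methods.md` for assumptions, parameter defaults and limits.

## Worked example

```python
from catgen import (CatalystCVAE, FixtureSpec, SamplingScheme,
                    TrainingConfig, evaluate_generation,
                    make_reaction_dataset)

ds = make_reaction_dataset(FixtureSpec(n_records=200, seed=7))   # synthetic
model = CatalystCVAE(ds.records, config=TrainingConfig.desk(epochs=25))
res = model.fit(seed=0)
print(res.summary())

out = res.generate(300, SamplingScheme(seed=1))
rep = evaluate_generation(out, [r.catalyst for r in res.split.train])
print({k: round(v, 3) for k, v in rep.as_dict().items()
       if isinstance(v, float)})
```

Output from this exact script:

```
Catalyst CVAE results
======================================================
records (train/val/test): 180/10/10
vocabulary: S=16, At=12, Bt=6 (flat dim 1744)
latent dim: 16   seed: 0
loss weights: alpha=1.0 beta=0.01 teacher forcing=0.25
epochs: 25 (augment x5), 88 s
final losses: total=18.51 recons=18.15 KL=32.820 pred=0.033
train: RMSE=3.03 MAE=2.41 R2=0.962 (n=180)
test : RMSE=7.09 MAE=5.97 R2=0.840 (n=10)
{'valid': 0.95, 'unique': 0.503, 'novel': 0.467, 'intdiv': 0.939, 'snn': 0.407}
```

Reading it: after 25 epochs on 200 synthetic reactions the joint loss has
fallen by ~64 % and the predictor explains most of the target variance
(the synthetic target is a known descriptor function plus σ=5 noise, so
the held-out RMSE of 7 approaches the noise floor); of 300 box-sampled
latents 95 % decode to sanitizable catalysts after post-processing, half
are structurally distinct and most of those are novel, internal diversity
is high (mean pairwise Tanimoto distance 0.94) and generated molecules
sit at moderate similarity (SNN 0.41) to the training set.

## Command line

```bash
catgen fixtures --n 500 --seed 1 --out runs/fx       # synthetic SURF-like CSV
catgen curate   --table runs/fx/reactions.csv --out runs/cur
catgen pretrain --table runs/cur/curated.csv --seed 0 --out runs/ck
catgen generate --checkpoint runs/ck --table runs/cur/curated.csv \
                --scheme random --n 100 --seed 1 --out runs/gen
catgen optimize --checkpoint runs/ck --table runs/cur/curated.csv \
                --rounds 10 --top-k 5 --seed 0 --out runs/opt
```

Every command writes a `provenance.json` (config, seed, package version,
input digests) next to its artifacts.
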