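# axonflow

Non-parametric prediction of **joint axon-diameter / g-ratio distributions**
from multi-contrast MRI, using a conditional normalizing flow pretrained on
histology-statistics-driven synthetic MRI and adapted to small paired
MRI/EM datasets by transfer learning.

## The problem

Biophysical models (NODDI, DTI, two-pool MT) compress a voxel's diffusion
and magnetization-transfer signal into a handful of scalars, and g-ratio
mapping combines them into a single aggregate
`g = 1 / sqrt(1 + MVF/AVF)` per voxel. But a white-matter voxel contains
hundreds of axons with a *distribution* of inner diameters `d` and g-ratios
`g = d_in / d_out`, and pathology (e.g. seizure-driven myelin remodeling)
can shift that distribution in ways a single aggregate hides. Training a
network to predict the full distribution requires paired MRI + electron
microscopy from the same tissue — which barely exists.

`axonflow` addresses the data-scarcity problem the way a transfer-learning
practitioner would:

1. **Synthetic substrates** — per-voxel axon populations (125 µm tiles,
   ≥ 400 axons, gamma-distributed diameters centered on 2.07 µm for the
   large-axon spinal-cord-like regime, copula-correlated g-ratios) stand in
   for segmented EM.
2. **Forward MRI physics** — each axon is an impermeable cylinder
   (Van Gelderen Gaussian-phase attenuation, d∥ = 0.35 µm²/ms), the
   extracellular space a tortuosity tensor `d⊥ = (1 − AVF) d∥`, mixed as
   `S = AVF Σᵢ (dᵢ²/Σⱼdⱼ²) sᵢ + ECF s_e`; myelin volume fraction converts
   to a bound-pool fraction (Φ_W,M = 0.475, β = 0.086) driving a two-pool
   MT-SPGR steady state; Rician noise at SNRs {32, 100, 316, 1000, 3160}.
3. **Conditional flow (cNFM)** — an MLP encoder (64/32/16, PReLU,
   batch norm) embeds the 90-channel signal vector; 7 fitted biophysical
   scalars (NODDI ICVF/ISO/OD, DTI FA/MD, MT F/k) are concatenated into a
   23-dimensional context conditioning two masked autoregressive blocks
   that map a bivariate Gaussian to `P(d, g | x)`.
4. **Pretraining + transfer** — NLL pretraining on 80% of the synthetic
   voxels with Jensen-Shannon-distance model selection; fine-tuning on a
   nine-subject mouse-like dataset with layer freezing and multi-task
   region/group classification heads, cross-validated over the 120 valid
   subject permutations.
5. **Evaluation** — base-2 Jensen-Shannon distance and KL divergence of
   predicted marginals against ground-truth histograms, percent error of
   the mean g-ratio, Cohen's d effect sizes, and a direct gamma-fit
   reference baseline.

Everything runs end-to-end on synthetic data; no external dataset is
needed. The network stack (reverse-mode autodiff, masked autoregressive
flow, Adam) is implemented in numpy inside the package.

## Worked example

```python
import numpy as np
from axonflow import (SubstrateParams, sample_population, filter_population,
                      builtin_presets, simulate_dataset, min_detectable_diameter)
from axonflow import biophys_maps, train

# 1. spinal-cord-like substrates (gamma diameters, mean ~2.07 um)
params = SubstrateParams(seed=42)
tiles = filter_population(sample_population(params, 120, seed=42), min_axons=400)
print(f"{len(tiles)} tiles, mean diameter "
      f"{np.concatenate([t.d_in for t in tiles]).mean():.2f} um")

# 2. two-shell diffusion + MT mouse protocol with Rician noise
dprot = builtin_presets("mouse_pretrain_diffusion")
mtprot = builtin_presets("mouse_pretrain_mt")
signals, vidx = simulate_dataset(tiles, dprot, mtprot,
                                 snrs=(100.0, 316.0, 1000.0), seed=43)
print(f"{len(signals)} voxels x {signals[0].x.size} channels")

# 3. fit the seven biophysical context maps
ds = train.assemble_dataset(tiles, signals, vidx, dprot.n_measurements,
                            mtprot.n_measurements)
maps = biophys_maps.fit_all_maps(ds.signals[:, :76], ds.signals[:, 76:],
                                 dprot, mtprot)
ds.maps = maps.context_matrix()

# 4. pretrain the conditional flow, score held-out voxels
res = train.pretrain(ds, train.TrainConfig(epochs=30, batch_voxels=64), seed=44)
m = train.marginal_jsd(res.model, ds, res.val_idx)
print(f"held-out JSD: diameter {m['jsd_d'].mean():.3f}, "
      f"g-ratio {m['jsd_g'].mean():.3f}")
print(f"resolution limit at 21 dB: {min_detectable_diameter(21):.2f} um")
```

Output:

```
120 tiles, mean diameter 2.03 um
360 voxels x 90 channels
held-out JSD: diameter 0.138, g-ratio 0.088
resolution limit at 21 dB: 1.21 um
```

The two JSD values say that, on voxels the model never saw, the predicted
axon-diameter and g-ratio marginal distributions sit within ~0.14 and
~0.09 (on the [0, 1] base-2 Jensen-Shannon scale) of the ground-truth
sample histograms — i.e. close to the resolution of a 50-bin histogram of
a few hundred axons. The 1.21 µm resolution limit is the smallest cylinder
diameter distinguishable from noise at this gradient strength and SNR;
predictions below it lean on the learned diameter–g-ratio correlation
rather than direct diffusion contrast.

The `axonflow` console script wires the same steps into cached pipeline
stages (`simulate`, `fit-maps`, `pretrain`, `finetune`, `evaluate`,
`ablate`, `full`), e.g.

```bash
axonflow full --seed 1 --out runs/demo
axonflow ablate --seed 1 --out runs/demo   # ablation comparison table
```

Density estimation is also exposed as a scikit-learn estimator
(`axonflow.train.ConditionalFlowDensity`) with `fit` / `predict` / `score`,
and the map fitters (`DTIFitter`, `TwoPoolMTFitter`, `ReducedNODDIFitter`)
as transformers.

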