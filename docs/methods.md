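# Methods

This note documents the models implemented in `axonflow`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
study does and does not establish about real data.

## Substrate generator

A *voxel substrate* is a list of axons — inner diameters `d` (µm) and
g-ratios `g = d_in/d_out` — standing in for the per-tile output of EM
segmentation. Only diameters and cross-sectional areas enter the forward
model, so no spatial packing is simulated; volume fractions are area sums
over a 125 × 125 µm tile:
`AVF = Σ π(d/2)²/A`, `MVF = Σ π[(d/2g)² − (d/2)²]/A`, `ECF = 1 − AVF − MVF`.

Marginals and coupling (defaults define the study conditions and are fixed):

- **Diameter**: gamma with shape 3.0 and scale chosen so the population
  mean is 2.07 µm (large-axon, spinal-cord-like regime). Shape 3 gives the
  right-skewed, CV ≈ 0.58 histograms typical of EM diameter data.
- **g-ratio**: Beta(35, 15) on (0, 1) — mean 0.70, sd ≈ 0.064, the normal
  white-matter range.
- **Coupling**: Gaussian copula with Spearman rank correlation +0.4
  (larger axons carry relatively thinner myelin), since joint EM clouds are
  visibly correlated but no generative law is published.
- **Per-voxel heterogeneity**: the voxel mean diameter is jittered by a
  mean-preserving lognormal (sd 0.12), the gamma shape by ±20%, and the
  g mean by ±0.04 — this is the across-voxel variation the conditional
  model has to learn.
- **Axon count**: Poisson with a per-voxel rate uniform in [500, 1100],
  then trimmed so total axon+myelin area stays below a 0.85 packing
  fraction (real white matter packs to ~0.8); a degenerate count range
  `(k, k)` yields exactly `k` axons. Tiles with fewer than 400 axons are
  excluded (inclusive threshold at 400).
- **Labels**: region (genu/body/splenium) and group (wildtype/mutant)
  labels can be assigned with configurable effects — region scales the
  mean diameter (0.90/1.00/1.10) and the mutant group shifts the g mean by
  −0.04 in genu and body only, mirroring the reported post-seizure
  de-myelination pattern — so the classification heads are trainable.

`scale_diameters` multiplies every diameter by a factor (0.15 maps the
2.07 µm regime onto the 0.31 µm mouse regime) and records the pre-scaling
MVF; MT simulation uses that frozen value so myelin content is held
constant while the diffusion geometry shrinks.

## Forward MRI model

**Diffusion.** Axons are impermeable infinite cylinders along the
through-plane axis; gradients decompose into axial and perpendicular
components. The perpendicular attenuation is the Van Gelderen finite-pulse
Gaussian-phase (GPD) series summed over Bessel-derivative roots (20 roots,
doubled until the last term contributes < 1e-8 relative). The parallel
component and the extracellular space are Gaussian, with
`d∥ = 0.35 µm²/ms` for both and tortuosity `d⊥ = (1 − AVF) d∥`. Signals mix
as `S = AVF Σᵢ (dᵢ²/Σdⱼ²) sᵢ + ECF s_e`; myelin is diffusion-invisible, so
the b = 0 level is exactly `1 − MVF` and is *not* renormalized to 1 — the
deficit itself carries myelin information the encoder may use.

*Validity*: a reflecting random-walk oracle confirms the GPD series to
better than 1% wherever `qR = γGδ·R ≲ 1`. Beyond that (d = 5 µm at the
625.5/600 mT/m maxima, qR ≈ 1.6–2.1) the phase distribution is platykurtic
(kurtosis ≈ 2.5) and the Gaussian-phase value overestimates the true
signal by several percent. This is an intrinsic limit of the GPD model
itself, shared by any simulator built on it; the test suite pins both the
1% agreement inside the validity regime and the sign/size of the deviation
outside it.

**Magnetization transfer.** Ground-truth MVF converts to a bound-pool
fraction by proton-volume bookkeeping
`F = MVF (1 − Φ_W,M) + β (1 − MVF)` with Φ_W,M = 0.475 (water fraction of
myelin) and β = 0.086 (non-myelin bound pool); the inverse is closed-form
and used when mapping fitted F back to MVF, keeping synthesis and analysis
consistent. MT-weighted SPGR signals use the continuous-wave
power-equivalent steady state of the coupled two-pool longitudinal
equations, with a super-Lorentzian bound-pool lineshape (on-resonance
clamped at 100 Hz) and Lorentzian direct saturation of the free pool,
normalized to the no-saturation signal. The equivalent flip angle θ maps
to `ω1_rms = θ/√(τ·TR)` with a 10 ms rectangular pulse. Pool constants are
explicit inputs (ex vivo range): T2_free 30 ms, T2_bound 11 µs, T1_free
1100 ms, R1_bound 1 s⁻¹, fundamental exchange rate 20 s⁻¹. A direct
Bloch-McConnell integration oracle agrees with the closed form to < 2%.

**Noise.** Rician: `v → √((v+n₁)² + n₂²)` with σ = S_ref/SNR, where S_ref
is the voxel's unattenuated normalized reference level (1.0). The default
ladder {32, 100, 316, 1000, 3160} replicates each substrate at five noise
levels, so 400 tiles become 2000 voxels.

## Biophysical context maps

Seven per-voxel scalars condition the flow: NODDI-style ICVF/ISO/OD, DTI
FA/MD, and MT F/k.

- **DTI**: weighted log-linear least squares (weights = squared signals)
  on the lower shell (b ≤ 4000 s/mm²) plus b = 0; eigenvalues clipped at
  zero.
- **Two-pool MT**: bounded nonlinear least squares for (F, k) with
  F ∈ (0, 0.5], k ∈ (0, 100] s⁻¹, multistart from four fixed
  initializations; non-convergence yields NaN sentinels and a pinned
  lower-bound F is flagged (flat curves carry no bound-pool information).
- **Reduced Watson-NODDI**: Watson-dispersed stick + axis-aligned
  tortuosity zeppelin + ball (d_iso = 2.0 µm²/ms, ex vivo free water),
  with d∥ fixed at 0.35 µm²/ms. κ is searched on a fixed 24-point log grid
  (0.25–64) with `OD = (2/π) arctan(1/κ)`, icvf on a 33-point grid with a
  closed-form conditional iso, then a bounded coordinate polish. This is a
  deliberate stand-in for full published NODDI (no per-voxel fiber
  direction search beyond the DTI principal eigenvector, zeppelin not
  orientation-dispersed); every fitter recovers its own forward model's
  parameters from noiseless data (inverse-crime tests).

Closed forms: the aggregate g-ratio `g = 1/√(1 + MVF/AVF)` with map-based
aggregation `AVF = (1 − MVF)(1 − ISO)·ICVF`, and the single-encoding
resolution limit
`d_min = (768/7 · σ D₀ / (γ² δ g_exp²))^{1/4}`. The noise term uses the
power-decibel convention `σ = 10^(−SNR_dB/10)`: this is the only reading
that reproduces 1.21 µm at the 21 dB reference point (the amplitude
convention would give ≈ 2.2 µm).

## Conditional flow model

Targets are transformed to `u = (log d, logit g)`, standardized by
training statistics, so the flow lives on ℝ²; reported densities carry the
full Jacobian correction. Two masked autoregressive (MADE-style) blocks
with a dimension flip in between map a bivariate standard normal to the
target; conditioner networks (2 hidden masked layers, 64 units, ReLU) see
the context as degree-0 inputs. Log-scales are soft-clamped to ±4 by a
tanh so the transform stays invertible under aggressive optimization
steps. The context is the 16-dimensional output of the signal encoder
(64/32/16 MLP, PReLU, batch norm before layers 2 and 3, optional dropout)
concatenated with the 7 standardized map values (23 total). Ablation
switches restrict the channels: `diffusion_only` (diffusion signal + 5
diffusion-derived maps), `mt_only` (MT signal + 2 MT maps), `no_maps`
(encoder output only), `no_multitask` (heads removed), `no_pretrain`
(random initialization), and fractional pretraining subsets.

Training minimizes the mean negative log-likelihood over all (d, g)
samples of a batch (the sum-form objective divided by batch size for
optimizer-scale stability; the transform's constant Jacobian terms are
added so the reported value is the true NLL). Each voxel contributes a
fixed-size random subsample of 32 pairs per step, balancing voxels with
different axon counts. Optimization is Adam with decoupled weight decay;
the sweep ranges are lr ∈ [1e-4, 1e-3] and weight decay ∈ [1e-6, 1e-5]
(defaults 5e-4 / 5e-6, the range midpoints). Batch normalization uses
batch statistics in training and running averages in evaluation, so
evaluation is deterministic.

Pretraining holds out 20% of voxels (1600/400 at the reference scale;
noisy replicates of one tile may fall on both sides, which matches the
voxel-level treatment of the tiles). Every second epoch the
validation Jensen-Shannon distance is computed on a fixed 60-voxel
monitor subset (50-bin marginals from a quadrature grid); the checkpoint
with the best mean of the two marginal JSDs is kept, with early stopping
at patience 20. Desk-scale defaults are 60 pretraining epochs and 40
fine-tuning epochs — enough for the validation JSD to plateau at the
reference problem size.

Fine-tuning starts from a pretrained checkpoint (a protocol fingerprint
guards against mismatched acquisition tables), optionally freezes
components (`encoder_layer_1..3`, `flow_block_1..2`; freezing is verified
by parameter hashes, and a fully frozen encoder switches its batch norms
to evaluation mode), and alternates one NLL batch with one cross-entropy
batch for the region and group heads (per-batch alternation is our
reading of "alternating"; the schedule is configurable). Model selection
ranks candidates by (a) mean percent error of the predicted mean g-ratio
on validation voxels and (b) the distance between predicted and
ground-truth Cohen's d per region over train+validation, combined by
tie-aware mean rank (the combination rule is a package choice and
replaceable).

Cross-validation enumerates all assignments of 2 wildtype + 3 mutant
subjects to training, 1 + 1 to validation, 1 + 1 to test, with the
missing-splenium subject constrained to training. For the default roster
(4 wildtype of which one is flagged, 5 mutant) the pool is exactly 120;
the enumeration is asserted against the combinatorial count. Note the
count is 120 only when the flagged subject is a wildtype (a flagged
mutant would give 144), which fixes the default roster's flag placement.

## Evaluation

Predicted joints are materialized on a quadrature grid over the working
rectangle `d ∈ (0, d_max]` (d_max = 3× the 99th percentile of training
diameters) × `g ∈ (0, 1)`; marginals are obtained by integrating over the
other axis and aggregating into the shared binning (default 50 bins per
axis; 25/100-bin sensitivity is reported alongside since metric values
depend on binning). The Jensen-Shannon *distance* uses base-2 logarithms
(bounded by 1); KLD is `KL(ground-truth histogram ‖ prediction)` in nats
with additive 1e-10 regularization, the direction that penalizes missing
mass where EM has support (configurable). The gamma reference fits a
maximum-likelihood gamma (location 0) to the samples and scores it under
the identical binning — the parametric baseline an experimentalist could
only compute with EM in hand. ROI densities are equal-weight mixtures of
per-voxel densities on a shared grid.

With a few hundred samples per voxel, the sample histogram itself sits at
a JSD of ~0.11–0.13 from its own generating distribution (multinomial
noise over 50 bins), so held-out JSDs approaching that floor indicate the
conditional density is essentially as close as the data can certify.

## What the synthetic study shows — and what it does not

Passing tests establish that the pipeline is self-consistent: the flow
recovers conditional distributions generated by this substrate law and
this forward physics, under this noise model. Real tissue adds effects
deliberately out of scope: non-circular and undulating axons, exchange,
T2 decay and distortions in the diffusion readout, slice-profile and
pulsed (non-CW) MT saturation, cell bodies and glia, EM segmentation
bias, and MRI/EM misregistration. Results on synthetic data therefore
bound what the architecture can do, not what it will achieve on scanner
data.

## Problem sizes and runtime choices

The reference synthetic study uses 400 tiles × 5 SNRs = 2000 voxels
(1600/400 split), 60 pretraining epochs with patience 20, and 50-bin
evaluation; it completes in a few minutes on one CPU. The transfer
demonstration uses 9 subjects × 3 regions (one subject missing its
splenium), ~200 EM pairs per ROI, one CV fold end-to-end in the `finetune`
stage, and the ablation grid reuses the cached simulation. The test-suite
oracles run scaled versions (reflecting random walks with 2×10⁴ walkers
and 5 µs steps; Bloch-McConnell integration to 60 s) chosen so each oracle
's Monte-Carlo error is well below the tolerance it guards.
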