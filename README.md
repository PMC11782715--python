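# walinet — water and lipid removal for ¹H MR spectroscopic imaging

Whole-brain proton MRSI measures a spectrum in every voxel of the
brain, but the metabolite resonances of interest sit orders of
magnitude below two nuisance signals: residual **water** around
4.68 ppm (raw water artifacts are 3–4 orders above the metabolites;
even after suppression pulses an asymmetric, heavy-tailed residual 1–2
orders above them remains) and **scalp lipids** (1–2 orders above the
metabolites, broad, overlapping the whole aliphatic region and leaked
into brain voxels by the ringing of limited k-space coverage).

This package is a self-contained toolkit for removing both. It is
aimed at MRSI methods researchers who want a nuisance-removal stage
they can train, calibrate, benchmark and plug into a processing
pipeline — together with the physics-based simulator needed to do all
of that without access to scanner data.

## What is inside

* **Y-Net nuisance identification** (`walinet.model`) — a 1-D
  convolutional network with two encoders and one decoder,

  𝒴(x1, x2) = y ≈ l + w,  m̃ = x1 − y,

  where x1 = m + l + w is the contaminated spectrum and
  x2 = (1 − ℒ)x1 its projection onto the lipid subspace. Four
  kernel-7 convolutional blocks per encoder/decoder (PReLU, dropout
  0.01, pooling/upsampling by 2, channels doubling from 16), skip
  connections from both encoders, extra blocks at the bottleneck and
  output. Phase augmentation (e^{iω}, ω ∈ [0, 2π)), normalization by
  𝔼 = ‖x1 − x2‖ and an MSE loss on real/imaginary channels follow the
  published recipe. A lipid-only twin ("lipnet") trains the same
  architecture on l alone. The network, its autodiff engine and Adam
  run on numpy/BLAS.
* **Lipid-L2 operator** (`walinet.lipid_l2`) — the conventional
  subspace penalty ℒ = (1 + βLLᴴ)⁻¹ built from scalp-voxel spectra,
  applied in factored SVD form, with β calibrated by bisection to the
  mean-absolute-diagonal setpoint mean(|diag ℒ|) = 0.938.
* **HLSVD water removal** (`walinet.hlsvd`) — damped-sinusoid
  decomposition of the FID (Hankel SVD, 32 retained components) and
  subtraction of the components inside 4.7 ± 0.5 ppm.
* **Simulation** (`walinet.spin_sim`, `walinet.nuisance`) — exact
  diagonalization of coupled spin systems (14-metabolite catalog at
  7 T), randomized concentrations/linewidths/noise/baselines,
  parametric lipid/water generators with "synthetic subjects", and a
  2D phantom whose scalp lipid contaminates brain voxels through
  k-space truncation ringing.
* **Post-processing** (`walinet.postproc`) — rank-40 low-rank
  spatiotemporal denoising (Casorati SVD), range-restricted NRMSE,
  suppression factors, SNR/FWHM proxies.
* **I/O and CLI** (`walinet.io`, `walinet.cli`) — an HDF5 container
  with provenance (seed, config hash), NIfTI-MRS import/export, ppm
  grid resampling between acquisition protocols, and a `walinet`
  command with `simulate-basis`, `make-phantom`, `make-dataset`,
  `train`, `apply` (walinet | lipnet | hlsvd-l2 | l2 | hlsvd),
  `evaluate` and `report` subcommands.

See `docs/methods.md` for the models, conventions and design
decisions, and `examples/` for one short runnable script per
capability.

## Worked example

Calibrate a lipid operator and clean a contaminated spectrum
(`examples/03_lipid_l2_operator.py`):

```text
calibrated beta = 0.422
mean |diag(L)| = 0.9370  (setpoint 0.938)
lipid-range magnitude before: 63901.5, after: 369.2, metabolite-only: 134.2
```

The operator reaches the 0.938 trade-off setpoint; applying ℒ to
m + lipid drops the 1.9–0.7 ppm magnitude by ~170× towards the
metabolite-only level — the remainder is lipid outside the span of the
50 scalp columns plus the small metabolite attenuation the setpoint
admits.

Train a small network and apply it to held-out subjects
(`examples/05_train_and_apply_network.py`, a few minutes on one core):

```text
epoch 0: train 1.11e-01 val 4.04e-02
...
epoch 5: train 4.77e-03 val 8.23e-03
lipid-range NRMSE: median 293.3% after removal (contaminated input: 3440%)
metabolite-range NRMSE: median 257.3% after removal (contaminated input: 3281%)
```

NRMSE is expressed relative to the metabolite ground-truth norm over
4.2–1.9 ppm, so the contaminated input sits far above 100 %; the
few-minute demo network removes over 90 % of the nuisance magnitude,
and the scaled study preset (more data, more epochs) goes further.

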