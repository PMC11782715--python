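# Methods

This note documents the models, algorithms and design choices behind
the package, and what the synthetic experiments do and do not show.

## Problem

Whole-brain proton MR spectroscopic imaging (MRSI) acquires a spectrum
in every voxel. Two nuisance signals dominate the raw spectra: water
(unsuppressed, 3–4 orders of magnitude above the metabolites; after
acquisition-level suppression typically 1–2 orders remain as an
asymmetric residual around 4.68 ppm) and scalp lipids (1–2 orders above
the metabolites, broad, spread over 0.9–5.3 ppm and leaked into brain
voxels by the point-spread function / Gibbs ringing of the limited
k-space coverage). The package implements three removal routes behind
one set of containers:

1. a Y-Net convolutional network that *identifies* the combined
   water+lipid signal y ≈ l + w of a spectrum so that the metabolite
   estimate is the subtraction m̃ = x1 − y ("walinet" mode; "lipnet"
   is the identical architecture trained for lipid only);
2. the conventional lipid-L2 subspace operator ℒ = (1 + βLLᴴ)⁻¹;
3. HLSVD water removal (damped-sinusoid modeling of the FID).

## Spectral conventions

A `SpectralAxis` fixes the grid: `n_points` FID samples at
`1/bandwidth_hz`, ppm decreasing with array index, and a rotating
component `exp(+2iπft)` appearing at `carrier_ppm + f/field_mhz`.
Defaults mirror the two acquisition protocols: 453 points / 2326 Hz
(3D) and 512 points / 4 kHz (2D) at 297.22 MHz (7 T), carrier at
4.65 ppm. All ppm intervals are closed and intersected with the grid
coverage; the 453-point/2326 Hz grid spans ≈0.74–8.56 ppm, so the
nominal 9.0–0.0 ppm "full" range is clipped accordingly.

## Spin-system simulation

Metabolites are simulated from first principles: the rotating-frame
Hamiltonian H = Σᵢ νᵢ Iᵢz + Σᵢ<ⱼ Jᵢⱼ Iᵢ·Iⱼ (frequency units; νᵢ the
carrier-relative shift in Hz) is diagonalized exactly, and the FID is
the sum over eigenstate pairs of |⟨r|I₊|s⟩|² exp(2iπ(Eᵣ−Eₛ)t)/2ⁿ⁻¹,
normalized so an uncoupled proton has unit amplitude. Strong coupling
is therefore exact, not first-order. Equivalent protons in a group are
expanded into individual spins with zero intra-group coupling; the
coupling graph is split into connected components, each capped at 8
spins (Hilbert space 256) — larger coupled networks raise an error
advising subgroup decomposition. T2 is mono-exponential (default
0.12 s, i.e. ≈2.7 Hz intrinsic Lorentzian width); the acquisition has
a sub-millisecond echo time, so no sequence evolution is modeled.

The bundled catalog (`data/metabolites.tsv`) holds 14 metabolites with
shifts/J from the standard proton tables, slightly simplified (e.g. the
NAAG and choline side chains are reduced) so every coupled network
stays within the cap. A physiological concentration ratio per
metabolite (NAA = 1) drives the sampler only.

### Randomized sampling

Training draws are m = Σ cₖ·basisₖ with cₖ ~ U[0,1] × ratioₖ, broadened
by an extra `linewidth_hz ~ U[4, 20]` Hz applied as a time-domain
envelope (Lorentzian `exp(−πgt)` adds exactly g Hz of FWHM; a drawn
fraction of the width uses the matched-FWHM Gaussian envelope, giving
Voigt-like lines), plus circular complex Gaussian noise in the time
domain with per-point σ log-uniform over two orders
(10^[−4,−2] × the FID amplitude), plus a smooth baseline of 3–6 very
broad (100–600 Hz) Gaussian bumps with random signs and phases at
±5 % of the metabolite amplitude.

## Nuisance generator and synthetic subjects

There is no public dataset of measured scalp-lipid/water spectra, so
the in vivo extraction step is replaced by a parametric generator.

* **Lipids**: broad Lorentzian resonances at 0.9, 1.3, 1.6, 2.0, 2.25,
  2.8, 4.4, 5.1, 5.3 ppm, linewidths 30–100 Hz, per-component amplitude
  profiles favoring the 1.3 ppm methylene peak, small frequency jitter
  (±0.05 ppm) and phase jitter (±0.5 rad); overall peak amplitude
  10^U[1,2] × the metabolite reference scale.
* **Water**: one narrow core plus four broad, offset, partially
  dephased components near 4.68 ppm, which produces the asymmetric
  heavy-tailed residual lineshape left by suppression pulses. The raw
  artifact model draws its amplitude at 10^U[3,4] × metabolites;
  training mixtures and phantoms use the post-suppression residual
  scale 10^U[1,2], the regime in which the energy normalization
  ‖x1 − x2‖ actually approximates the metabolite-signal energy.
  Sidebands are available but off by default.
* **Metabolite reference scale**: the spectral peak magnitude of the
  catalog at half-maximal concentrations with a 10 Hz line; all
  nuisance amplitudes are expressed in orders of magnitude above it.

A **synthetic subject** is one draw of the generator hyper-values
(per-component amplitude/linewidth regimes, a global center offset,
water-width regime); all spectra of a subject share them. Each subject
also gets its own lipid basis and β-calibrated operator. Training and
evaluation sets are assembled from disjoint subject-id blocks and RNG
streams, and the train/validation split inside training is
subject-wise, so no subject's nuisance statistics leak across
partitions.

The 2D phantom places metabolites in an elliptical brain (WM interior,
GM rim at +25 %), lipids and water in a scalp annulus, synthesizes the
spatio-spectral data at `hires_factor`× the acquisition matrix, and
truncates k-space centrally with no apodization (worst-case ringing;
optional Hamming flag). Brain-voxel lipid contamination then arises
mechanistically from the truncation, as in vivo.

## Lipid-L2 operator

ℒ = (1 + βLLᴴ)⁻¹ is never densified: with the thin SVD L = USVᴴ,
ℒx = x − U diag(βs²/(1+βs²)) Uᴴx, cost O(n_freq·rank), singular values
below 1e−8 of the largest truncated. diag(ℒ) = 1 − Σₖ wₖ|Uᵢₖ|² gives
the calibration statistic without forming the matrix. β is bisected on
log₁₀β — the mean absolute diagonal decreases monotonically from 1 to
1 − rank/n_freq — until it reaches the conventional setpoint 0.938
within 1e−3. The operator acts on frequency-domain vectors over the
full grid (a ppm-window option exists). (1−ℒ)x1 is both the network's
second input and the "lipid-only" projection; ℒx is the conventional
suppressed spectrum. One operator per subject/phantom.

## HLSVD water removal

State-space (Kung) estimation: Hankel matrix of size
⌈N/2⌉ × (N−⌈N/2⌉+1) (near-square, standard practice), truncated SVD to
32 components (dense LAPACK for N ≤ 1024, iterative solver above),
poles from the shift invariance of the left singular vectors by least
squares, amplitudes/phases from a linear fit of the FID onto the pole
dictionary. Mildly growing exponentials (pole magnitude ≤ 1.02) are
retained and flagged by their negative damping; poles beyond that clamp
are noise artifacts whose powers overflow the linear fit and are
dropped. Components whose frequency maps into 4.7 ± 0.5 ppm are
reconstructed and subtracted from the FID — a model-based subtraction
that also removes the in-window components' tails across the whole
spectrum.

## Y-Net

Two encoders (for x1 and x2 = (1−ℒ)x1, each as 2 real/imaginary
channels) and one decoder. Four blocks per encoder/decoder; a block is
two same-padded convolutions of kernel size 7, each followed by PReLU
and dropout 0.01; max-pooling / linear-upsampling by 2 between blocks;
channels start at `base_channels` (16 published, 8 in the scaled
preset) and double per pooling (16→32→64→128). The encoder outputs are
concatenated into an extra bottleneck block; skip connections from
*both* encoders are channel-concatenated into the decoder at matching
scales; one extra block follows the decoder before a final kernel-7
projection to 2 channels. Inputs of arbitrary length are zero-padded on
the right to the next multiple of 2⁴ and cropped after the last layer
(453 → 464).

Training follows the published recipe: per example a shared random
phase e^{iω}, ω ~ U[0, 2π), multiplies x1, x2 and the target; the pair
is normalized by 𝔼 = ‖x1 − x2‖ (an eps floor guards x1 = x2); the loss
is MSE between network output and target/𝔼 on the separated
real/imaginary channels; Adam (β₁ = 0.9, β₂ = 0.999). The published
schedule (lr 0.01 quartered every 50 of 400 epochs) is the
`TrainConfig` default; at desk scale (batch 32, float32) that rate is
unstable, so the scaled study preset uses lr 3e−3 with a global
gradient-norm clip of 5 and the same quarter-decay applied over thirds
of the epoch budget — chosen on training/validation convergence of a
pilot run, not on evaluation metrics. Training, data order,
initialization and dropout are all driven by one seed; the validation
split is subject-wise. At inference, x2 and 𝔼 are recomputed per
spectrum, the output is de-normalized by the same 𝔼 (which makes
inference exactly scale-equivariant), and m̃ = x1 − y.

The network engine itself (reverse-mode autodiff over im2col/BLAS 1-D
convolutions, PReLU, dropout, pooling, linear upsampling,
concatenation, MSE; Adam) is part of the package and is exercised by
numerical gradient checks in the test suite.

## Low-rank denoising and metrics

* `low_rank_denoise`: truncated SVD of the Casorati (voxel × time)
  matrix to rank K = 40 — by Eckart–Young the optimal separable
  m(r,t) = Σₙ Uₙ(r)Vₙ(t) approximation in the Frobenius norm.
* `nrmse`: 100·‖pred − truth‖₂ over a closed ppm range, divided by the
  L2 norm of the ground-truth *metabolite* spectrum over 4.2–1.9 ppm.
  The single metabolite-strength denominator (instead of a per-range
  truth norm, available as an option) makes lipid- and water-range
  residuals directly comparable to the metabolite signal; residuals
  larger than the metabolite signal therefore read as > 100 %.
  Standard ranges: 9.0–0.0 (clipped to the grid), 4.2–1.9 (metabolite),
  1.9–0.7 (lipid) ppm.
* `suppression_factor`: mean over mask voxels of the ratio of in-range
  L2 magnitudes before/after processing (lipid range 1.9–0.7, water
  range 4.2–5.2 ppm); vanishing post-processing energy is capped at
  1e6 and flagged.
* `snr_fwhm`: peak real-part height near 2.008 ppm over the real-part
  standard deviation in a signal-free range, and the linearly
  interpolated half-maximum width; a zero noise floor returns the
  capped SNR. These are simple proxies, not spectral-fitting estimates.

## Scaled study and problem sizes

`walinet.study.run_study` generates 6000 training spectra from 20
synthetic subjects and 1000 evaluation spectra from 4 held-out
subjects (200-column lipid basis per subject, matching the scalp-voxel
counts of the acquisition geometries), trains the scaled network
(base 8, 15 epochs, batch 32) and evaluates per-spectrum range-NRMSE of
the network against the conventional L2 and HLSVD+L2 baselines, the
baselines using the evaluation subject's own calibrated operator. The
whole study runs in roughly ten minutes on one CPU core. The full
preset mirroring the published configuration (1.9×10⁶ spectra, 400
epochs, 16 base channels) is defined but is a GPU-scale computation.

## What the synthetic experiments show — and what they cannot

The generator reproduces the *mechanisms* (subspace structure of scalp
lipid, heavy-tailed residual water, ringing leakage, subject-wise
pooling) but not the full complexity of measured data. Two consequences
matter when reading results:

* Synthetic water and lipid are finite sums of damped sinusoids — the
  exact model class of HLSVD. The conventional HLSVD(+L2) baseline is
  therefore close to an oracle on this data, a flattery the in vivo
  comparison does not extend to it.
* The desk-scale network sees roughly four orders of magnitude fewer
  example-presentations than the published training (6000×15 versus
  1.9×10⁶×400 on GPU hardware). It learns the gross nuisance structure
  (it clearly beats doing nothing, and improves on the plain L2
  operator in the metabolite range) but does not reach the precision
  regime of the published network, and on this synthetic benchmark it
  does not overtake the near-oracle HLSVD+L2 baseline. The
  network-versus-baseline comparisons at published effect sizes should
  be read as requiring published-scale training.

## Known limitations

* No macromolecule background, B0 inhomogeneity maps, coil modeling,
  or 3D phantoms; relaxation is mono-exponential T2.
* The metabolite catalog simplifies some spin systems; it is a
  superset-friendly plain-text file, so richer tables can be dropped in.
* NRMSE denominator and suppression-factor formulas are explicit
  package conventions (documented above), selectable where alternatives
  exist.
* Checkpoints store raw parameter arrays plus a JSON sidecar; they are
  portable only across identical architecture configs.
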