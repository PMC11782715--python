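"""Synthetic lipid and water nuisance signals and an MRSI phantom.

Scalp lipids are modeled as a superposition of broad resonances at the
standard aliphatic/olefinic positions (0.9-5.3 ppm) with randomized
amplitudes, linewidths, small frequency jitter and phases; their overall
amplitude is drawn 1-2 orders of magnitude above the metabolite scale.
Residual water is a superposition of components of very different
widths and phases around 4.68 ppm, producing the asymmetric lineshape
with heavy tails left by suppression pulses; its amplitude is drawn 3-4
orders of magnitude above the metabolite scale.

A "synthetic subject" is one draw of the nuisance hyper-parameters
(component amplitude profiles, linewidth regimes, center offsets): all
spectra of one subject share those hyper-values, mirroring the
subject-wise pooling of measured nuisance data.  Training and
evaluation sets are assembled from disjoint subjects.

The 2D phantom places metabolites inside an elliptical brain and
lipids+water in a scalp annulus at high spatial resolution; truncating
its k-space to the acquisition matrix produces the Gibbs ringing that
leaks scalp lipid into brain voxels, which is the contamination
mechanism the removal methods are evaluated on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .axis import SpectralAxis
from .lipid_l2 import LipidSubspace, build_subspace
from .spectrum import MRSIVolume, Spectrum
from .spin_sim import (
    MetaboliteBasis,
    MetaboliteRanges,
    sample_metabolite_spectrum,
    sample_params,
)

__all__ = [
    "LipidComponent",
    "NuisanceParams",
    "PhantomVolume",
    "TrainingDataset",
    "sample_lipid_spectrum",
    "sample_water_spectrum",
    "draw_subject_params",
    "reference_scale",
    "build_phantom",
    "assemble_training_set",
]


@dataclass(frozen=True)
class LipidComponent:
    center_ppm: float
    linewidth_hz: tuple[float, float]
    rel_amp: tuple[float, float]


#: Default scalp-lipid resonances (standard literature positions); the
#: 1.3 ppm methylene peak dominates, olefinic/glyceride peaks at 4.4-5.3
#: ppm sit close to water.
DEFAULT_LIPID_COMPONENTS = (
    LipidComponent(0.90, (30.0, 100.0), (0.30, 0.80)),
    LipidComponent(1.30, (30.0, 100.0), (0.50, 1.00)),
    LipidComponent(1.60, (30.0, 100.0), (0.20, 0.60)),
    LipidComponent(2.00, (30.0, 100.0), (0.20, 0.60)),
    LipidComponent(2.25, (30.0, 100.0), (0.10, 0.40)),
    LipidComponent(2.80, (30.0, 100.0), (0.05, 0.30)),
    LipidComponent(4.40, (30.0, 100.0), (0.05, 0.30)),
    LipidComponent(5.10, (30.0, 100.0), (0.05, 0.30)),
    LipidComponent(5.30, (30.0, 100.0), (0.05, 0.25)),
)


@dataclass(frozen=True)
class NuisanceParams:
    """Hyper-parameters of the nuisance generator.

    Scales are log10 intervals relative to the metabolite reference
    scale (the spectral peak magnitude of a nominal metabolite
    profile): lipids 1-2 orders above metabolites; raw water artifacts
    3-4 orders.  Training mixtures and phantoms use
    ``water_residual_orders`` instead — the residual water left after
    acquisition-level suppression (WET pulses), 1-2 orders above
    metabolites, which is the regime the removal methods actually see
    and the one in which the energy normalization ||x1 - x2||
    approximates the metabolite signal energy.
    """

    lipid_components: tuple[LipidComponent, ...] = DEFAULT_LIPID_COMPONENTS
    lipid_scale_orders: tuple[float, float] = (1.0, 2.0)
    water_center: float = 4.68
    water_components: int = 5
    water_width_hz: tuple[float, float] = (8.0, 150.0)
    water_scale_orders: tuple[float, float] = (3.0, 4.0)
    water_residual_orders: tuple[float, float] = (1.0, 2.0)
    freq_jitter_ppm: float = 0.05
    phase_jitter_rad: float = 0.5
    sideband_freqs_hz: tuple[float, ...] = ()
    sideband_amp_fraction: float = 0.0

    def __post_init__(self) -> None:
        for c in self.lipid_components:
            if not 0.0 <= c.center_ppm <= 6.0:
                raise ValueError(f"lipid center {c.center_ppm} ppm outside [0, 6]")
            if c.linewidth_hz[0] < 4.0:
                raise ValueError(
                    "lipid linewidths must be at least metabolite-like (>= 4 Hz)"
                )
        if not 0.0 <= self.water_center <= 6.0:
            raise ValueError("water center outside [0, 6] ppm")
        if self.water_components < 1:
            raise ValueError("need at least one water component")


def _lorentz_fid(
    t: np.ndarray, f_hz: float, width_hz: float, amp: float, phase: float
) -> np.ndarray:
    return amp * np.exp(1j * phase) * np.exp((2j * np.pi * f_hz - np.pi * width_hz) * t)


def _scale_to(spec_fid: np.ndarray, axis: SpectralAxis, peak: float) -> np.ndarray:
    """Scale an FID so its spectrum's peak magnitude equals ``peak``."""
    mag = np.abs(axis.fid_to_spectrum(spec_fid))
    m = mag.max()
    return spec_fid * (peak / m) if m > 0 else spec_fid


def sample_lipid_spectrum(
    params: NuisanceParams,
    axis: SpectralAxis,
    seed: int | np.random.Generator,
    ref_scale: float = 1.0,
) -> Spectrum:
    """One random scalp-lipid spectrum (frequency domain).

    Peak magnitude is ``ref_scale * 10**U[lipid_scale_orders]``; an
    amplitude interval of [0, 0] on every component yields zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = axis.time
    fid = np.zeros(axis.n_points, dtype=complex)
    for c in params.lipid_components:
        amp = rng.uniform(*c.rel_amp)
        width = rng.uniform(*c.linewidth_hz)
        jitter = rng.uniform(-params.freq_jitter_ppm, params.freq_jitter_ppm)
        phase = rng.uniform(-params.phase_jitter_rad, params.phase_jitter_rad)
        f = axis.ppm_to_hz(c.center_ppm + jitter)
        fid += _lorentz_fid(t, f, width, amp, phase)
    scale = ref_scale * 10.0 ** rng.uniform(*params.lipid_scale_orders)
    fid = _scale_to(fid, axis, scale) if np.any(fid) else fid
    return Spectrum(axis.fid_to_spectrum(fid), axis, "freq")


def sample_water_spectrum(
    params: NuisanceParams,
    axis: SpectralAxis,
    seed: int | np.random.Generator,
    ref_scale: float = 1.0,
) -> Spectrum:
    """One random residual-water spectrum (frequency domain).

    The first component is narrow and sets the peak; the others are
    broad, slightly offset and partially dephased, which makes the
    tails larger than a symmetric absorption line.  Optional sidebands
    replicate the water at +/- the configured harmonic frequencies.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = axis.time
    fid = np.zeros(axis.n_points, dtype=complex)
    w_lo, w_hi = params.water_width_hz
    for i in range(params.water_components):
        if i == 0:
            width = rng.uniform(w_lo, 2.0 * w_lo)
            amp = 1.0
            offset = rng.uniform(-0.02, 0.02)
            phase = rng.uniform(-0.2, 0.2)
        else:
            width = rng.uniform(min(2.0 * w_lo, w_hi), w_hi)
            amp = rng.uniform(0.2, 0.8)
            offset = rng.uniform(-0.1, 0.1)
            phase = rng.uniform(-params.phase_jitter_rad, params.phase_jitter_rad)
        f = axis.ppm_to_hz(params.water_center + offset)
        fid += _lorentz_fid(t, f, width, amp, phase)
    if params.sideband_amp_fraction > 0.0:
        core = fid.copy()
        for fh in params.sideband_freqs_hz:
            mod = params.sideband_amp_fraction * np.exp(2j * np.pi * fh * t)
            fid += core * (mod + np.conj(mod))
    scale = ref_scale * 10.0 ** rng.uniform(*params.water_scale_orders)
    fid = _scale_to(fid, axis, scale) if np.any(fid) else fid
    return Spectrum(axis.fid_to_spectrum(fid), axis, "freq")


def draw_subject_params(
    base: NuisanceParams, rng: np.random.Generator
) -> NuisanceParams:
    """One synthetic subject: narrowed hyper-intervals inside ``base``.

    Per subject the lipid amplitude profile, linewidth regime and a
    global center offset are fixed; individual spectra still vary
    within the narrowed intervals.
    """
    center_shift = rng.uniform(-0.03, 0.03)
    lw_factor = rng.uniform(0.8, 1.25)
    comps = []
    for c in base.lipid_components:
        a_lo, a_hi = c.rel_amp
        a = rng.uniform(a_lo, a_hi)
        half = 0.15 * (a_hi - a_lo)
        w_lo, w_hi = c.linewidth_hz
        w = np.clip(rng.uniform(w_lo, w_hi) * lw_factor, w_lo, w_hi)
        w_half = 0.15 * (w_hi - w_lo)
        comps.append(
            LipidComponent(
                center_ppm=c.center_ppm + center_shift,
                linewidth_hz=(
                    float(np.clip(w - w_half, w_lo, w_hi)),
                    float(np.clip(w + w_half, w_lo, w_hi)),
                ),
                rel_amp=(
                    float(np.clip(a - half, a_lo, a_hi)),
                    float(np.clip(a + half, a_lo, a_hi)),
                ),
            )
        )
    w_lo, w_hi = base.water_width_hz
    w_mid = rng.uniform(w_lo, 0.5 * (w_lo + w_hi))
    return replace(
        base,
        lipid_components=tuple(comps),
        water_width_hz=(float(w_mid), float(w_hi)),
    )


def reference_scale(basis: MetaboliteBasis, rel_conc: dict[str, float]) -> float:
    """Spectral peak magnitude of the nominal (mid-range) metabolite profile.

    Nuisance amplitudes are expressed in orders of magnitude above this
    scale, which corresponds to metabolite peaks at half the maximum
    physiological concentration with a 10 Hz line.
    """
    from .spin_sim import MetaboliteSampleParams

    conc = {n: 0.5 * rel_conc.get(n, 1.0) for n in basis.names}
    params = MetaboliteSampleParams(concentrations=conc, linewidth_hz=10.0)
    spec = sample_metabolite_spectrum(basis, params)
    return float(np.abs(spec.data).max())


# ----------------------------------------------------------------------
# phantom
# ----------------------------------------------------------------------

@dataclass
class PhantomVolume:
    """Ground-truth spatial maps of the phantom at high resolution."""

    grid_shape: tuple[int, int]
    hires_factor: int
    brain_mask: np.ndarray
    scalp_mask: np.ndarray
    concentration_maps: dict[str, np.ndarray]
    lipid_amplitude: np.ndarray
    water_amplitude: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.brain_mask & self.scalp_mask):
            raise RuntimeError("phantom generator bug: brain and scalp masks overlap")
        if np.any(self.lipid_amplitude[~self.scalp_mask] != 0.0):
            raise RuntimeError(
                "phantom generator bug: lipid amplitude nonzero outside scalp"
            )


def _ellipse(shape: tuple[int, int], ry: float, rx: float) -> np.ndarray:
    ny, nx = shape
    y = (np.arange(ny) - (ny - 1) / 2.0) / (ny / 2.0)
    x = (np.arange(nx) - (nx - 1) / 2.0) / (nx / 2.0)
    yy, xx = np.meshgrid(y, x, indexing="ij")
    return (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0


def _downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    ny, nx = mask.shape
    blocks = mask.reshape(ny // factor, factor, nx // factor, factor)
    return blocks.mean(axis=(1, 3)) > 0.5


def truncate_kspace(
    hires: np.ndarray, shape: tuple[int, int], apodize: bool = False
) -> np.ndarray:
    """Low-resolution image of a high-resolution spatial map.

    2D FFT, central k-space crop to ``shape``, inverse FFT; no
    apodization by default (worst-case Gibbs ringing), optionally a
    Hamming window over the retained k-space.
    """
    ny, nx = shape
    k = np.fft.fftshift(np.fft.fft2(hires, axes=(0, 1)), axes=(0, 1))
    cy, cx = hires.shape[0] // 2, hires.shape[1] // 2
    k = k[cy - ny // 2 : cy - ny // 2 + ny, cx - nx // 2 : cx - nx // 2 + nx]
    if apodize:
        wy = np.hamming(ny)[:, None]
        wx = np.hamming(nx)[None, :]
        k = k * (wy * wx)[(...,) + (None,) * (k.ndim - 2)]
    img = np.fft.ifft2(np.fft.ifftshift(k, axes=(0, 1)), axes=(0, 1))
    # keep per-area signal amplitude: FFT crop rescales by the matrix ratio
    img *= (ny * nx) / (hires.shape[0] * hires.shape[1])
    return img


def build_phantom(
    shape: tuple[int, int],
    params: NuisanceParams,
    basis: MetaboliteBasis,
    rel_conc: dict[str, float],
    seed: int = 0,
    hires_factor: int = 4,
    linewidth_hz: float = 10.0,
    noise_sigma_rel: float = 3e-4,
    lipid_on: bool = True,
    water_on: bool = True,
    apodize: bool = False,
) -> tuple[PhantomVolume, MRSIVolume]:
    """Simulate a 2D MRSI acquisition with scalp-lipid ringing.

    Returns the high-resolution ground truth and the k-space-truncated
    voxel grid (time domain) with brain/scalp masks at acquisition
    resolution.
    """
    if hires_factor < 2:
        raise ValueError("hires_factor must be >= 2")
    rng = np.random.default_rng(seed)
    axis = basis.axis
    ny, nx = shape
    hy, hx = ny * hires_factor, nx * hires_factor

    brain = _ellipse((hy, hx), 0.68, 0.60)
    skull_outer = _ellipse((hy, hx), 0.92, 0.84)
    skull_inner = _ellipse((hy, hx), 0.84, 0.76)
    scalp = skull_outer & ~skull_inner
    assert not np.any(brain & scalp)

    # metabolite concentration maps: WM interior, GM rim, mild texture
    gm_rim = brain & ~_ellipse((hy, hx), 0.50, 0.44)
    conc_maps = {}
    for name in basis.names:
        level = rel_conc.get(name, 1.0)
        base_map = np.where(brain, 0.8, 0.0) + np.where(gm_rim, 0.25, 0.0)
        texture = 1.0 + 0.1 * rng.standard_normal()
        conc_maps[name] = level * base_map * texture

    ref = reference_scale(basis, rel_conc)
    lipid_amp = np.zeros((hy, hx))
    if lipid_on:
        lipid_amp[scalp] = np.exp(rng.normal(0.0, 0.3, scalp.sum()))
    water_amp = np.zeros((hy, hx))
    if water_on:
        water_amp[brain] = np.exp(rng.normal(0.0, 0.2, brain.sum()))
        water_amp[scalp] = 0.5 * np.exp(rng.normal(0.0, 0.2, scalp.sum()))

    phantom = PhantomVolume(
        grid_shape=shape,
        hires_factor=hires_factor,
        brain_mask=brain,
        scalp_mask=scalp,
        concentration_maps=conc_maps,
        lipid_amplitude=lipid_amp,
        water_amplitude=water_amp,
    )

    # spatio-spectral synthesis at high resolution, in the time domain
    t = axis.time
    fids = basis.fid_matrix()  # (n_met, n_t)
    conc_stack = np.stack([conc_maps[n] for n in basis.names], axis=-1)
    env = np.exp(-np.pi * linewidth_hz * t)
    data = (conc_stack.reshape(hy * hx, -1) @ fids) * env
    data = data.reshape(hy, hx, axis.n_points)

    sub_params = draw_subject_params(params, rng)
    if lipid_on:
        idx = np.argwhere(scalp)
        lip = np.zeros((idx.shape[0], axis.n_points), dtype=complex)
        for row, (iy, ix) in enumerate(idx):
            lip[row] = (
                sample_lipid_spectrum(sub_params, axis, rng, ref_scale=ref)
                .to_time()
                .data
            ) * lipid_amp[iy, ix]
        data[scalp] += lip
    if water_on:
        residual_params = replace(
            sub_params, water_scale_orders=sub_params.water_residual_orders
        )
        wat_shape = (
            sample_water_spectrum(residual_params, axis, rng, ref_scale=ref)
            .to_time()
            .data
        )
        data += water_amp[..., None] * wat_shape

    low = truncate_kspace(data, shape, apodize=apodize)
    if noise_sigma_rel > 0:
        sigma = noise_sigma_rel * ref
        low = low + sigma * (
            rng.standard_normal(low.shape) + 1j * rng.standard_normal(low.shape)
        ) / np.sqrt(2.0)

    brain_lo = _downsample_mask(brain, hires_factor)
    scalp_lo = _downsample_mask(scalp, hires_factor)
    scalp_lo &= ~brain_lo
    volume = MRSIVolume(low, axis, "time", brain_mask=brain_lo, scalp_mask=scalp_lo)
    return phantom, volume


# ----------------------------------------------------------------------
# training-set assembly
# ----------------------------------------------------------------------

@dataclass
class TrainingDataset:
    """Paired training arrays plus per-subject lipid operators.

    All spectral arrays are frequency domain, shape (n, n_points).
    ``x1 = m + l + w`` and ``x2 = (1 - L_s) x1`` with the subject's own
    lipid operator; ``m`` contains noise and baseline of the draw.
    """

    axis: SpectralAxis
    m: np.ndarray
    lipid: np.ndarray
    water: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    subject_ids: np.ndarray
    subspaces: dict[int, LipidSubspace]
    ref_scale: float

    def __len__(self) -> int:
        return self.x1.shape[0]

    def arrays(self, mode: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if mode == "walinet":
            return self.x1, self.x2, self.lipid + self.water
        if mode == "lipnet":
            return self.x1, self.x2, self.lipid
        raise ValueError("mode must be 'walinet' or 'lipnet'")

    def metabolite_truth(self) -> np.ndarray:
        return self.m


def assemble_training_set(
    n: int,
    mode: str,
    basis: MetaboliteBasis,
    rel_conc: dict[str, float],
    params: NuisanceParams | None = None,
    ranges: MetaboliteRanges | None = None,
    n_subjects: int = 10,
    n_basis_spectra: int = 50,
    seed: int = 0,
    subject_id_offset: int = 0,
    include_water: bool | None = None,
) -> TrainingDataset:
    """n training examples grouped into synthetic subjects.

    Each subject gets its own nuisance hyper-draw, its own lipid basis
    (``n_basis_spectra`` scalp spectra) and a beta-calibrated operator;
    x2 is computed with the subject's operator.  ``mode`` selects the
    target convention downstream ('lipnet' drops water from both x1 and
    the target unless ``include_water`` overrides).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if mode not in ("walinet", "lipnet"):
        raise ValueError("mode must be 'walinet' or 'lipnet'")
    if include_water is None:
        include_water = mode == "walinet"
    params = params or NuisanceParams()
    ranges = ranges or MetaboliteRanges()
    axis = basis.axis
    ref = reference_scale(basis, rel_conc)
    rng = np.random.default_rng(seed)

    npts = axis.n_points
    m = np.empty((n, npts), dtype=complex)
    lip = np.empty((n, npts), dtype=complex)
    wat = np.zeros((n, npts), dtype=complex)
    x2 = np.empty((n, npts), dtype=complex)
    subject_ids = np.empty(n, dtype=int)
    subspaces: dict[int, LipidSubspace] = {}

    per_subject = [n // n_subjects] * n_subjects
    for i in range(n % n_subjects):
        per_subject[i] += 1

    row = 0
    for s in range(n_subjects):
        sid = subject_id_offset + s
        sub_params = draw_subject_params(params, rng)
        # mixtures carry post-suppression residual water
        residual_params = replace(
            sub_params, water_scale_orders=sub_params.water_residual_orders
        )
        L = np.stack(
            [
                sample_lipid_spectrum(sub_params, axis, rng, ref_scale=ref).data
                for _ in range(n_basis_spectra)
            ],
            axis=1,
        )
        subspace = build_subspace(L, axis)
        subspaces[sid] = subspace
        for _ in range(per_subject[s]):
            mp = sample_params(basis, rel_conc, rng, ranges)
            m[row] = sample_metabolite_spectrum(basis, mp).data
            lip[row] = sample_lipid_spectrum(sub_params, axis, rng, ref_scale=ref).data
            if include_water:
                wat[row] = sample_water_spectrum(
                    residual_params, axis, rng, ref_scale=ref
                ).data
            subject_ids[row] = sid
            # per-spectrum projection so x2 is bit-reproducible from x1
            x2[row] = subspace.project(m[row] + lip[row] + wat[row])
            row += 1

    x1 = m + lip + wat
    return TrainingDataset(
        axis=axis,
        m=m,
        lipid=lip,
        water=wat,
        x1=x1,
        x2=x2,
        subject_ids=subject_ids,
        subspaces=subspaces,
        ref_scale=ref,
    )
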