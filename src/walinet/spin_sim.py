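"""Quantum-mechanical simulation of metabolite spectra.

A metabolite is described as a system of coupled spin-1/2 protons with
chemical shifts (ppm) and scalar couplings (Hz).  The free-precession
Hamiltonian in the rotating frame, in frequency units,

    H = sum_i nu_i I_iz + sum_{i<j} J_ij (I_i . I_j),

with ``nu_i = (delta_i - carrier_ppm) * field_mhz`` the offset of proton
i in Hz, is diagonalized exactly, so strong-coupling effects (second
order multiplets, "roofing") come out of the physics rather than from
first-order multiplet rules.  The observable FID is the sum over
eigenstate pairs (r, s) of

    |<r| I+ |s>|^2 exp(+2i pi (E_r - E_s) t) / 2^(n-1),

which gives every uncoupled proton unit amplitude at t = 0.  A
mono-exponential T2 decay is applied on top.

The module also provides the randomized metabolite-spectrum sampler used
to build training data: concentration-weighted basis mixtures with extra
Lorentzian/Gaussian line broadening, a smooth spline-free baseline made
of very broad Gaussian bumps, and circular complex Gaussian noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .axis import SpectralAxis
from .spectrum import Spectrum

__all__ = [
    "SpinSystem",
    "MetaboliteBasis",
    "MetaboliteSampleParams",
    "MetaboliteRanges",
    "simulate_metabolite_fid",
    "build_basis",
    "sample_metabolite_spectrum",
    "sample_params",
    "load_catalog",
    "default_systems",
    "MAX_COUPLED_SPINS",
]

#: Largest coupled network simulated exactly (Hilbert space 2^8 = 256).
MAX_COUPLED_SPINS = 8


class SpinCountError(RuntimeError):
    """A coupled spin network exceeds the exact-diagonalization cap."""


@dataclass(frozen=True)
class SpinSystem:
    """Coupled proton system of one metabolite.

    ``shifts`` and ``multiplicities`` are per proton *group*;
    ``couplings`` is the symmetric J matrix between groups in Hz
    (couplings inside a group of equivalent protons are unobservable and
    taken as zero).
    """

    name: str
    shifts: tuple[float, ...]
    couplings: np.ndarray
    multiplicities: tuple[int, ...]
    t2: float = 0.12

    def __post_init__(self) -> None:
        j = np.asarray(self.couplings, dtype=float)
        n = len(self.shifts)
        if j.shape != (n, n):
            raise ValueError(f"{self.name}: J matrix must be {n}x{n}, got {j.shape}")
        if not np.allclose(j, j.T):
            raise ValueError(f"{self.name}: J matrix must be symmetric")
        if not np.allclose(np.diag(j), 0.0):
            raise ValueError(f"{self.name}: J matrix diagonal must be zero")
        if any(m < 1 for m in self.multiplicities):
            raise ValueError(f"{self.name}: multiplicities must be >= 1")
        if len(self.multiplicities) != n:
            raise ValueError(f"{self.name}: need one multiplicity per group")
        if any(not (0.0 <= s <= 10.0) for s in self.shifts):
            raise ValueError(f"{self.name}: shifts must lie in [0, 10] ppm")
        if self.t2 <= 0:
            raise ValueError(f"{self.name}: t2 must be positive")
        object.__setattr__(self, "couplings", j)

    @property
    def n_protons(self) -> int:
        return int(sum(self.multiplicities))

    def expand(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-proton shifts and J matrix (groups expanded to spins)."""
        idx = np.repeat(np.arange(len(self.shifts)), self.multiplicities)
        shifts = np.asarray(self.shifts, float)[idx]
        j = self.couplings[np.ix_(idx, idx)].copy()
        # equivalent protons of one group: no observable intra-group coupling
        same = idx[:, None] == idx[None, :]
        j[same] = 0.0
        return shifts, j


@dataclass
class MetaboliteBasis:
    """Unit-concentration spectra of a metabolite catalog on one axis."""

    axis: SpectralAxis
    entries: dict[str, Spectrum]

    def __post_init__(self) -> None:
        for name, spec in self.entries.items():
            if spec.axis != self.axis:
                raise ValueError(f"basis entry {name!r} is on a different axis")
            if not np.all(np.isfinite(spec.data.view(float))):
                raise ValueError(f"basis entry {name!r} contains non-finite values")

    @property
    def names(self) -> list[str]:
        return list(self.entries)

    def fid_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Stack of time-domain unit FIDs, shape (n_metabolites, n_points)."""
        names = names or self.names
        return np.stack([self.entries[n].to_time().data for n in names])


# ----------------------------------------------------------------------
# exact simulation
# ----------------------------------------------------------------------

def _spin_ops(n: int) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Single-spin operators Ix, Iy, Iz embedded in the n-spin space."""
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    eye = np.eye(2, dtype=complex)
    ix, iy, iz = [], [], []
    for k in range(n):
        ops = [eye] * n
        for op, out in ((sx, ix), (sy, iy), (sz, iz)):
            ops[k] = op
            m = ops[0]
            for o in ops[1:]:
                m = np.kron(m, o)
            out.append(m)
        ops[k] = eye
    return ix, iy, iz


def _component_fid(
    shifts_hz: np.ndarray, j: np.ndarray, t: np.ndarray, amp_tol: float = 1e-12
) -> np.ndarray:
    """FID of one coupled network (shifts already in Hz offsets)."""
    n = len(shifts_hz)
    ix, iy, iz = _spin_ops(n)
    h = np.zeros((2**n, 2**n), dtype=complex)
    for i in range(n):
        h += shifts_hz[i] * iz[i]
    for i in range(n):
        for k in range(i + 1, n):
            if j[i, k] != 0.0:
                h += j[i, k] * (ix[i] @ ix[k] + iy[i] @ iy[k] + iz[i] @ iz[k])
    evals, vecs = np.linalg.eigh(h)
    iplus = sum(x + 1j * y for x, y in zip(ix, iy))
    a = vecs.conj().T @ iplus @ vecs
    amps = np.abs(a) ** 2 / 2 ** (n - 1)
    freqs = evals[:, None] - evals[None, :]
    keep = amps > amp_tol * amps.max()
    amps, freqs = amps[keep], freqs[keep]
    return (amps[None, :] * np.exp(2j * np.pi * t[:, None] * freqs[None, :])).sum(axis=1)


def _coupled_components(j: np.ndarray) -> list[np.ndarray]:
    """Indices of connected components of the coupling graph."""
    n = j.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for k in np.nonzero(j[i] != 0.0)[0]:
                if not seen[k]:
                    seen[k] = True
                    stack.append(k)
        comps.append(np.array(sorted(comp)))
    return comps


def simulate_metabolite_fid(system: SpinSystem, axis: SpectralAxis) -> Spectrum:
    """Unit-concentration time-domain signal of one spin system.

    The coupling graph is split into its connected components, each of
    which is diagonalized exactly; components larger than
    :data:`MAX_COUPLED_SPINS` raise :class:`SpinCountError` with advice
    to decompose the system into subgroups.
    """
    shifts_ppm, j = system.expand()
    shifts_hz = (shifts_ppm - axis.carrier_ppm) * axis.field_mhz
    t = axis.time
    fid = np.zeros(axis.n_points, dtype=complex)
    for comp in _coupled_components(j):
        if len(comp) > MAX_COUPLED_SPINS:
            raise SpinCountError(
                f"{system.name}: coupled network of {len(comp)} spins exceeds the "
                f"cap of {MAX_COUPLED_SPINS}; split the system into independently "
                f"simulated subgroups"
            )
        if len(comp) == 1:
            # closed form: single uncoupled proton
            fid += np.exp(2j * np.pi * shifts_hz[comp[0]] * t)
        else:
            fid += _component_fid(shifts_hz[comp], j[np.ix_(comp, comp)], t)
    fid *= np.exp(-t / system.t2)
    return Spectrum(fid, axis, "time")


def build_basis(systems: list[SpinSystem], axis: SpectralAxis) -> MetaboliteBasis:
    """Simulate every system on a shared axis. Deterministic."""
    if not systems:
        raise ValueError("need at least one spin system")
    names = [s.name for s in systems]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate spin-system names: {dupes}")
    entries = {s.name: simulate_metabolite_fid(s, axis) for s in systems}
    return MetaboliteBasis(axis=axis, entries=entries)


# ----------------------------------------------------------------------
# catalog
# ----------------------------------------------------------------------

def load_catalog(path=None) -> tuple[list[SpinSystem], dict[str, float]]:
    """Parse the tab-separated spin-system catalog.

    Returns the systems plus the relative physiological concentration of
    each metabolite (used by the randomized sampler).
    """
    if path is None:
        source = (
            importlib.resources.files("walinet") / "data" / "metabolites.tsv"
        ).read_text()
    else:
        with open(path) as fh:
            source = fh.read()
    systems: list[SpinSystem] = []
    rel_conc: dict[str, float] = {}
    for line in source.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(f"catalog line has {len(fields)} fields, expected 5: {line!r}")
        name, groups_s, j_s, t2_s, rel_s = fields
        shifts, mults = [], []
        for g in groups_s.split(";"):
            shift, mult = g.split(":")
            shifts.append(float(shift))
            mults.append(int(mult))
        n = len(shifts)
        j = np.zeros((n, n))
        if j_s != "-":
            for item in j_s.split(";"):
                pair, val = item.split(":")
                i, k = (int(x) - 1 for x in pair.split("-"))
                j[i, k] = j[k, i] = float(val)
        systems.append(
            SpinSystem(name, tuple(shifts), j, tuple(mults), t2=float(t2_s))
        )
        rel_conc[name] = float(rel_s)
    return systems, rel_conc


def default_systems() -> list[SpinSystem]:
    return load_catalog()[0]


# ----------------------------------------------------------------------
# randomized sampling
# ----------------------------------------------------------------------

@dataclass
class MetaboliteSampleParams:
    """One concrete draw of a randomized metabolite spectrum."""

    concentrations: dict[str, float]
    linewidth_hz: float = 0.0
    gauss_fraction: float = 0.0
    baseline_coeffs: tuple[float, ...] = ()
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linewidth_hz < 0:
            raise ValueError("linewidth_hz must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValueError("gauss_fraction must lie in [0, 1]")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be nonnegative")


@dataclass
class MetaboliteRanges:
    """Sampling ranges of the synthetic training distribution.

    Concentrations are ``U[0, 1]`` times the catalog's physiological
    ratio per metabolite; linewidth broadening is uniform in Hz; the
    per-point time-domain noise standard deviation is log-uniform over
    two orders of magnitude relative to the drawn FID amplitude; the
    baseline is a sum of 3-6 very broad (> 100 Hz) Gaussian bumps of
    random sign.
    """

    linewidth_hz: tuple[float, float] = (4.0, 20.0)
    gauss_fraction: tuple[float, float] = (0.0, 0.5)
    noise_rel_orders: tuple[float, float] = (-4.0, -2.0)
    n_baseline_bumps: tuple[int, int] = (3, 6)
    baseline_rel_amp: float = 0.05
    baseline_min_width_hz: float = 100.0


def sample_params(
    basis: MetaboliteBasis,
    rel_conc: dict[str, float],
    rng: np.random.Generator,
    ranges: MetaboliteRanges | None = None,
) -> MetaboliteSampleParams:
    """Draw randomized sampling parameters from the training ranges."""
    ranges = ranges or MetaboliteRanges()
    conc = {
        name: float(rng.uniform(0.0, 1.0)) * rel_conc.get(name, 1.0)
        for name in basis.names
    }
    lw = float(rng.uniform(*ranges.linewidth_hz))
    gf = float(rng.uniform(*ranges.gauss_fraction))
    # reference FID amplitude of this draw (sum of proton-weighted conc)
    fid0 = sum(
        conc[n] * abs(basis.entries[n].to_time().data[0]) for n in basis.names
    )
    sigma = fid0 * 10.0 ** rng.uniform(*ranges.noise_rel_orders)
    n_bumps = int(rng.integers(ranges.n_baseline_bumps[0], ranges.n_baseline_bumps[1] + 1))
    coeffs = tuple(
        float(rng.uniform(-1.0, 1.0)) * ranges.baseline_rel_amp * fid0
        for _ in range(n_bumps)
    )
    seed = int(rng.integers(0, 2**31 - 1))
    return MetaboliteSampleParams(
        concentrations=conc,
        linewidth_hz=lw,
        gauss_fraction=gf,
        baseline_coeffs=coeffs,
        noise_sigma=sigma,
        seed=seed,
    )


def _broadening_envelope(
    t: np.ndarray, linewidth_hz: float, gauss_fraction: float
) -> np.ndarray:
    """Time-domain envelope adding ``linewidth_hz`` FWHM to every line.

    A fraction of the width is Gaussian (Voigt-like line), the rest
    Lorentzian.  ``exp(-pi*g*t)`` adds exactly g Hz of Lorentzian FWHM;
    the Gaussian part uses the matched-FWHM envelope
    ``exp(-(pi*g*t)^2 / (4 ln 2))``.
    """
    gl = linewidth_hz * (1.0 - gauss_fraction)
    gg = linewidth_hz * gauss_fraction
    env = np.exp(-np.pi * gl * t)
    if gg > 0:
        env = env * np.exp(-((np.pi * gg * t) ** 2) / (4.0 * np.log(2.0)))
    return env


def sample_metabolite_spectrum(
    basis: MetaboliteBasis, params: MetaboliteSampleParams
) -> Spectrum:
    """Concentration-weighted, broadened, noisy metabolite spectrum.

    Returns the frequency-domain spectrum
    ``FFT[(sum_k c_k fid_k) * envelope + noise] + baseline``.
    Identical params (including seed) give bit-identical output.
    """
    unknown = sorted(set(params.concentrations) - set(basis.names))
    if unknown:
        raise ValueError(f"unknown metabolite names: {unknown}")
    axis = basis.axis
    t = axis.time
    fid = np.zeros(axis.n_points, dtype=complex)
    for name, c in params.concentrations.items():
        if c != 0.0:
            fid += c * basis.entries[name].to_time().data
    if params.linewidth_hz > 0:
        fid *= _broadening_envelope(t, params.linewidth_hz, params.gauss_fraction)
    rng = np.random.default_rng(params.seed)
    if params.noise_sigma > 0:
        noise = params.noise_sigma * (
            rng.standard_normal(axis.n_points) + 1j * rng.standard_normal(axis.n_points)
        ) / np.sqrt(2.0)
        fid = fid + noise
    spec = axis.fid_to_spectrum(fid)
    if params.baseline_coeffs:
        spec = spec + _baseline(axis, params.baseline_coeffs, rng)
    return Spectrum(spec, axis, "freq")


def _baseline(
    axis: SpectralAxis, coeffs: tuple[float, ...], rng: np.random.Generator
) -> np.ndarray:
    """Smooth complex baseline: very broad Gaussian bumps, random phase.

    Bump amplitudes are expressed in FID units and converted to spectral
    height so that ``baseline_rel_amp`` is relative to metabolite peaks.
    """
    f = axis.freq_hz
    lo, hi = f.min(), f.max()
    base = np.zeros(axis.n_points, dtype=complex)
    # spectral height of a unit-amplitude FID line with ~10 Hz width
    unit_height = 1.0 / (1.0 - np.exp(-np.pi * 10.0 / axis.bandwidth_hz))
    for c in coeffs:
        center = rng.uniform(lo, hi)
        width = rng.uniform(100.0, 600.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        base += (
            c * unit_height * np.exp(1j * phase)
            * np.exp(-0.5 * ((f - center) / width) ** 2)
        )
    return base
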