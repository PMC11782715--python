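"""HLSVD water removal: damped-sinusoid modeling of the FID.

The FID is modeled as a sum of exponentially damped complex sinusoids.
Parameters are estimated with the state-space (Kung) method: a Hankel
matrix built from the FID is truncated to the requested model order by
SVD, the signal poles follow from the shift-invariance of the left
singular vectors, and amplitudes/phases from a linear fit of the FID
onto the estimated exponentials.  Water removal reconstructs the
components whose frequency falls inside a ppm window (conventionally
4.7 +/- 0.5 ppm) and subtracts them from the FID; everything outside
the window is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .axis import SpectralAxis
from .spectrum import Spectrum

__all__ = ["DampedSinusoid", "hankel_decompose", "remove_water", "reconstruct"]

#: Conventional model order: number of retained Hankel singular values.
DEFAULT_N_COMPONENTS = 32

#: Conventional water window in ppm.
DEFAULT_WATER_WINDOW = (4.7 - 0.5, 4.7 + 0.5)

#: Above this FID length the truncated SVD switches to an iterative solver.
_DENSE_SVD_MAX = 1024


@dataclass(frozen=True)
class DampedSinusoid:
    """One estimated FID component  a * exp(i*phi) * exp((-d + 2i*pi*f) t)."""

    frequency: float  # Hz
    damping: float  # 1/s; positive = decaying, negative = growing (flagged)
    amplitude: float  # >= 0
    phase: float  # radians

    @property
    def growing(self) -> bool:
        return self.damping < 0

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        return (
            self.amplitude
            * np.exp(1j * self.phase)
            * np.exp((-self.damping + 2j * np.pi * self.frequency) * t)
        )


def hankel_decompose(
    fid: Spectrum | np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
    dwell_time: float | None = None,
    max_pole_magnitude: float = 1.02,
) -> list[DampedSinusoid]:
    """Estimate damped sinusoids from a time-domain signal.

    The Hankel matrix has shape ``ceil(N/2) x (N - ceil(N/2) + 1)``
    (near square, standard practice).  Components are returned sorted by
    decreasing energy.  An all-zero FID yields an empty list.

    Mildly growing exponentials (pole magnitude up to
    ``max_pole_magnitude``) are retained and flagged via their negative
    damping, as is common HLSVD practice; poles beyond the clamp are
    noise artifacts whose powers overflow the linear fit and are
    rejected.
    """
    if isinstance(fid, Spectrum):
        dwell_time = fid.axis.dwell_time
        y = fid.to_time().data
    else:
        y = np.asarray(fid, dtype=complex)
        if dwell_time is None:
            raise ValueError("dwell_time required when fid is a bare array")
    n = y.size
    if n < 2 * n_components:
        raise ValueError(
            f"FID of length {n} is too short for {n_components} components "
            f"(need at least {2 * n_components} points)"
        )
    if not np.any(y):
        return []
    rows = (n + 1) // 2
    cols = n - rows + 1
    H = scipy.linalg.hankel(y[:rows], y[rows - 1 :])
    assert H.shape == (rows, cols)
    k = min(n_components, rows - 1, cols - 1)
    if max(rows, cols) <= _DENSE_SVD_MAX:
        u, _, _ = np.linalg.svd(H, full_matrices=False)
        u = u[:, :k]
    else:
        u, s, _ = scipy.sparse.linalg.svds(H, k=k)
        u = u[:, np.argsort(s)[::-1]]
    # shift invariance: U_down Z ~= U_up  ->  poles are eigenvalues of Z
    z_mat, *_ = np.linalg.lstsq(u[:-1], u[1:], rcond=None)
    poles = np.linalg.eigvals(z_mat)
    mags = np.abs(poles)
    poles = poles[(mags > 1e-12) & (mags <= max_pole_magnitude)]
    if poles.size == 0:
        return []
    # linear fit of the full FID onto the exponential dictionary
    t_idx = np.arange(n)
    basis = np.power.outer(poles, t_idx).T  # (n, k)
    coeff, *_ = np.linalg.lstsq(basis, y, rcond=None)
    dt = dwell_time
    comps = []
    for z, c in zip(poles, coeff):
        if abs(c) == 0.0:
            continue
        comps.append(
            DampedSinusoid(
                frequency=float(np.angle(z) / (2.0 * np.pi * dt)),
                damping=float(-np.log(np.abs(z)) / dt),
                amplitude=float(np.abs(c)),
                phase=float(np.angle(c)),
            )
        )
    # sort by component energy over the sampled window
    def energy(cmp: DampedSinusoid) -> float:
        d = np.exp(-2.0 * cmp.damping * dt)
        if d >= 1.0:
            return cmp.amplitude**2 * n
        return cmp.amplitude**2 * (1.0 - d**n) / (1.0 - d)

    comps.sort(key=energy, reverse=True)
    return comps


def reconstruct(
    components: list[DampedSinusoid], axis: SpectralAxis
) -> Spectrum:
    """Time-domain signal of a list of damped sinusoids."""
    t = axis.time
    y = np.zeros(axis.n_points, dtype=complex)
    for c in components:
        y += c.evaluate(t)
    return Spectrum(y, axis, "time")


def remove_water(
    fid: Spectrum,
    window_ppm: tuple[float, float] = DEFAULT_WATER_WINDOW,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> Spectrum:
    """Subtract modeled components whose frequency lies in a ppm window.

    Returns the time-domain residual.  The model-based subtraction also
    removes the tails that in-window components spread across the whole
    spectrum, which a simple spectral mask could not.
    """
    axis = fid.axis
    lo, hi = sorted(window_ppm)
    pmin, pmax = axis.ppm_range()
    if hi < pmin or lo > pmax:
        raise ValueError(
            f"water window {window_ppm} ppm lies outside the spectral range "
            f"({pmin:.2f}, {pmax:.2f}) ppm"
        )
    y = fid.to_time()
    comps = hankel_decompose(y, n_components=n_components)
    in_window = [
        c for c in comps if lo <= axis.hz_to_ppm(c.frequency) <= hi
    ]
    if not in_window:
        return y.copy()
    water = reconstruct(in_window, axis)
    return Spectrum(y.data - water.data, axis, "time")
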