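"""Spectral axis: the frequency/time grid shared by all spectra.

The axis fixes the conventions used throughout the package:

* the FID is sampled at ``dt = 1/bandwidth_hz``;
* a positive rotating component ``exp(+2i*pi*f*t)`` appears at offset
  ``f`` Hz from the carrier, i.e. at ``carrier_ppm + f/field_mhz`` ppm;
* spectra are indexed with ppm *decreasing* along the array, so index 0
  is the left (high-ppm) edge as spectra are conventionally plotted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralAxis", "AXIS_3D", "AXIS_2D"]


@dataclass(frozen=True)
class SpectralAxis:
    """Frequency grid of an MRS acquisition.

    Parameters
    ----------
    n_points:
        Number of FID/spectral points.
    bandwidth_hz:
        Spectral bandwidth (sampling rate) in Hz.
    carrier_ppm:
        Chemical shift at zero frequency offset (transmitter position).
    field_mhz:
        Proton Larmor frequency in MHz; converts Hz offsets to ppm.
    """

    n_points: int
    bandwidth_hz: float
    carrier_ppm: float = 4.65
    field_mhz: float = 297.22

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError(f"n_points must be positive, got {self.n_points}")
        if self.bandwidth_hz <= 0:
            raise ValueError(f"bandwidth_hz must be positive, got {self.bandwidth_hz}")
        if self.field_mhz <= 0:
            raise ValueError(f"field_mhz must be positive, got {self.field_mhz}")

    # -- time domain -------------------------------------------------
    @property
    def dwell_time(self) -> float:
        return 1.0 / self.bandwidth_hz

    @property
    def time(self) -> np.ndarray:
        """Sampling times of the FID in seconds."""
        return np.arange(self.n_points) * self.dwell_time

    # -- frequency domain --------------------------------------------
    @property
    def freq_hz(self) -> np.ndarray:
        """Frequency offsets in Hz, decreasing with index."""
        f = np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_time))
        return f[::-1].copy()

    @property
    def ppm(self) -> np.ndarray:
        """Chemical-shift axis in ppm, decreasing with index."""
        return self.carrier_ppm + self.freq_hz / self.field_mhz

    @property
    def hz_per_point(self) -> float:
        return self.bandwidth_hz / self.n_points

    @property
    def ppm_per_point(self) -> float:
        return self.hz_per_point / self.field_mhz

    def ppm_range(self) -> tuple[float, float]:
        """(min, max) chemical shift covered by the grid."""
        p = self.ppm
        return float(p[-1]), float(p[0])

    # -- conversions --------------------------------------------------
    def ppm_to_hz(self, ppm: float) -> float:
        return (ppm - self.carrier_ppm) * self.field_mhz

    def hz_to_ppm(self, hz: float) -> float:
        return self.carrier_ppm + hz / self.field_mhz

    def index_of_ppm(self, ppm: float) -> int:
        """Index of the spectral point nearest to ``ppm``."""
        return int(np.argmin(np.abs(self.ppm - ppm)))

    def ppm_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of points inside the closed ppm interval.

        The interval may be given in either order and is intersected
        with the grid coverage.
        """
        lo, hi = (lo, hi) if lo <= hi else (hi, lo)
        p = self.ppm
        return (p >= lo) & (p <= hi)

    # -- FFT conventions ----------------------------------------------
    def fid_to_spectrum(self, fid: np.ndarray) -> np.ndarray:
        """Discrete spectrum of an FID, on the descending-ppm grid."""
        s = np.fft.fftshift(np.fft.fft(fid, axis=-1), axes=-1)
        return s[..., ::-1].copy()

    def spectrum_to_fid(self, spec: np.ndarray) -> np.ndarray:
        s = np.fft.ifftshift(spec[..., ::-1], axes=-1)
        return np.fft.ifft(s, axis=-1)


#: Default grid of the high-resolution 3D FID-MRSI protocol (7T).
AXIS_3D = SpectralAxis(n_points=453, bandwidth_hz=2326.0)

#: Grid of the 2D Cartesian FID-MRSI protocol (7T).
AXIS_2D = SpectralAxis(n_points=512, bandwidth_hz=4000.0)
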