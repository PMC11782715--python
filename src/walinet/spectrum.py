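"""In-memory containers: single-voxel spectra and MRSI voxel grids."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axis import SpectralAxis

__all__ = ["Spectrum", "MRSIVolume"]

_DOMAINS = ("time", "freq")


@dataclass
class Spectrum:
    """One voxel's complex signal together with its spectral axis.

    ``domain`` records whether ``data`` holds the FID ("time") or its
    discrete spectrum ("freq"); conversions go through the axis' FFT
    conventions so a round trip is exact to floating precision.
    """

    data: np.ndarray
    axis: SpectralAxis
    domain: str = "time"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.shape != (self.axis.n_points,):
            raise ValueError(
                f"data has shape {self.data.shape}, expected ({self.axis.n_points},)"
            )
        if self.domain not in _DOMAINS:
            raise ValueError(f"domain must be one of {_DOMAINS}, got {self.domain!r}")

    def to_time(self) -> "Spectrum":
        if self.domain == "time":
            return self
        return Spectrum(self.axis.spectrum_to_fid(self.data), self.axis, "time")

    def to_freq(self) -> "Spectrum":
        if self.domain == "freq":
            return self
        return Spectrum(self.axis.fid_to_spectrum(self.data), self.axis, "freq")

    def copy(self) -> "Spectrum":
        return Spectrum(self.data.copy(), self.axis, self.domain)

    # Convenience arithmetic; both operands must share axis and domain.
    def _check(self, other: "Spectrum") -> None:
        if other.axis != self.axis:
            raise ValueError("spectral axes differ")
        if other.domain != self.domain:
            raise ValueError("domains differ")

    def __add__(self, other: "Spectrum") -> "Spectrum":
        self._check(other)
        return Spectrum(self.data + other.data, self.axis, self.domain)

    def __sub__(self, other: "Spectrum") -> "Spectrum":
        self._check(other)
        return Spectrum(self.data - other.data, self.axis, self.domain)

    def __mul__(self, c: complex) -> "Spectrum":
        return Spectrum(self.data * c, self.axis, self.domain)

    __rmul__ = __mul__

    def norm(self, range_ppm: tuple[float, float] | None = None) -> float:
        """L2 norm of the spectrum, optionally over a closed ppm range."""
        s = self.to_freq()
        if range_ppm is None:
            return float(np.linalg.norm(s.data))
        mask = self.axis.ppm_mask(*range_ppm)
        return float(np.linalg.norm(s.data[mask]))


@dataclass
class MRSIVolume:
    """A 2D spatial grid of spectra plus anatomical masks.

    ``data`` has shape ``(ny, nx, n_points)``; masks are boolean maps of
    shape ``(ny, nx)``.  Brain and scalp masks are disjoint.
    """

    data: np.ndarray
    axis: SpectralAxis
    domain: str = "time"
    brain_mask: np.ndarray | None = None
    scalp_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 3 or self.data.shape[-1] != self.axis.n_points:
            raise ValueError(
                f"data must be (ny, nx, {self.axis.n_points}), got {self.data.shape}"
            )
        if self.domain not in _DOMAINS:
            raise ValueError(f"domain must be one of {_DOMAINS}, got {self.domain!r}")
        shape = self.grid_shape
        for name in ("brain_mask", "scalp_mask"):
            m = getattr(self, name)
            if m is None:
                setattr(self, name, np.zeros(shape, dtype=bool))
            else:
                m = np.asarray(m, dtype=bool)
                if m.shape != shape:
                    raise ValueError(f"{name} has shape {m.shape}, expected {shape}")
                setattr(self, name, m)
        if np.any(self.brain_mask & self.scalp_mask):
            raise ValueError("brain and scalp masks overlap")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def voxel(self, iy: int, ix: int) -> Spectrum:
        return Spectrum(self.data[iy, ix], self.axis, self.domain)

    def casorati(self) -> np.ndarray:
        """Voxel x time (or frequency) matrix, row-major voxel order."""
        return self.data.reshape(self.n_voxels, self.axis.n_points)

    def to_freq(self) -> "MRSIVolume":
        if self.domain == "freq":
            return self
        return MRSIVolume(
            self.axis.fid_to_spectrum(self.data), self.axis, "freq",
            self.brain_mask, self.scalp_mask,
        )

    def to_time(self) -> "MRSIVolume":
        if self.domain == "time":
            return self
        return MRSIVolume(
            self.axis.spectrum_to_fid(self.data), self.axis, "time",
            self.brain_mask, self.scalp_mask,
        )

    def with_data(self, data: np.ndarray, domain: str | None = None) -> "MRSIVolume":
        return MRSIVolume(
            data, self.axis, domain or self.domain, self.brain_mask, self.scalp_mask
        )
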