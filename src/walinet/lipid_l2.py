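"""Lipid subspace suppression operator  L = (1 + beta L L^H)^-1.

``L`` (n_freq x n_lipid) collects frequency-domain spectra of scalp
voxels; ``beta`` trades lipid suppression against metabolite
preservation.  Applying the operator to a spectrum x gives the
lipid-suppressed spectrum (the conventional "lipid L2 regularization"
baseline), while ``(1 - L)x`` approximately projects x onto the lipid
subspace span(L) and serves as the second input of the Y-Net.

The operator is never densified: with the thin SVD ``L = U S V^H``,

    (1 + beta L L^H)^-1 = I - U diag(w) U^H,   w_k = beta s_k^2 / (1 + beta s_k^2),

so application costs O(n_freq * rank) and the diagonal needed for beta
calibration is ``1 - sum_k w_k |U_ik|^2``.  beta is calibrated by
bisection on log10(beta), using the fact that the mean absolute
diagonal decreases monotonically from 1 (beta -> 0) to its floor
(beta -> inf); the conventional setpoint is 0.938.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .axis import SpectralAxis
from .spectrum import MRSIVolume, Spectrum

__all__ = [
    "LipidSubspace",
    "extract_lipid_basis",
    "calibrate_beta",
    "lipid_project",
    "apply_l2_suppression",
    "build_subspace",
    "CalibrationError",
    "DIAG_SETPOINT",
]

#: Conventional setpoint for the mean absolute diagonal of the operator.
DIAG_SETPOINT = 0.938

#: Singular values below this fraction of the largest are truncated.
_RANK_RTOL = 1e-8


class CalibrationError(RuntimeError):
    pass


@dataclass
class LipidSubspace:
    """Factored lipid suppression operator for one subject."""

    L: np.ndarray
    beta: float
    axis: SpectralAxis
    U: np.ndarray = field(init=False, repr=False)
    s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=complex)
        if L.ndim != 2:
            raise ValueError("L must be a 2-D matrix (n_freq x n_lipid)")
        if L.shape[0] != self.axis.n_points:
            raise ValueError(
                f"L has {L.shape[0]} rows but the axis has {self.axis.n_points} points"
            )
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        self.L = L
        u, s, _ = np.linalg.svd(L, full_matrices=False)
        keep = s > _RANK_RTOL * (s[0] if s.size else 0.0)
        self.U, self.s = u[:, keep], s[keep]

    @property
    def rank(self) -> int:
        return int(self.s.size)

    def _weights(self, beta: float | None = None) -> np.ndarray:
        beta = self.beta if beta is None else beta
        bs2 = beta * self.s**2
        return bs2 / (1.0 + bs2)

    def apply(self, x: np.ndarray, beta: float | None = None) -> np.ndarray:
        """L x  (lipid-suppressed spectrum), on frequency-domain vectors."""
        return x - self.project(x, beta)

    def project(self, x: np.ndarray, beta: float | None = None) -> np.ndarray:
        """(1 - L) x  (approximate projection onto span(L))."""
        w = self._weights(beta)
        coeff = self.U.conj().T @ x
        return self.U @ (w * coeff.T).T if coeff.ndim > 1 else self.U @ (w * coeff)

    def diagonal(self, beta: float | None = None) -> np.ndarray:
        """diag(L) without forming the dense operator (real, in (0, 1])."""
        w = self._weights(beta)
        return 1.0 - (np.abs(self.U) ** 2) @ w

    def mean_abs_diag(self, beta: float | None = None) -> float:
        return float(np.mean(np.abs(self.diagonal(beta))))

    def with_beta(self, beta: float) -> "LipidSubspace":
        return LipidSubspace(self.L, beta, self.axis)


def extract_lipid_basis(volume: MRSIVolume, scalp_mask: np.ndarray) -> np.ndarray:
    """Matrix of scalp-voxel spectra, one column per voxel (row-major).

    The volume is converted to the frequency domain if needed.
    """
    scalp_mask = np.asarray(scalp_mask, dtype=bool)
    if scalp_mask.shape != volume.grid_shape:
        raise ValueError(
            f"scalp mask shape {scalp_mask.shape} does not match grid {volume.grid_shape}"
        )
    if not scalp_mask.any():
        raise ValueError("scalp mask is empty")
    spectra = volume.to_freq().casorati()[scalp_mask.ravel()]
    bad = ~np.all(np.isfinite(spectra.view(float)), axis=1)
    if bad.any():
        voxel = np.flatnonzero(scalp_mask.ravel())[np.argmax(bad)]
        iy, ix = divmod(int(voxel), volume.grid_shape[1])
        raise ValueError(f"scalp voxel ({iy}, {ix}) contains non-finite values")
    return spectra.T.copy()


def calibrate_beta(
    L: np.ndarray | LipidSubspace,
    axis: SpectralAxis | None = None,
    target: float = DIAG_SETPOINT,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> float:
    """beta such that mean(|diag(L)|) hits ``target`` within ``tol``.

    Bisection on log10(beta); the mean diagonal is monotonically
    decreasing in beta, from 1 down to ``1 - rank/n_freq`` in the limit.
    """
    if isinstance(L, LipidSubspace):
        sub = L
    else:
        if axis is None:
            axis = SpectralAxis(n_points=np.asarray(L).shape[0], bandwidth_hz=1.0)
        sub = LipidSubspace(L, 0.0, axis)
    if sub.rank == 0:
        raise CalibrationError("lipid basis is zero: diag(L) = 1 for every beta")
    floor = 1.0 - sub.rank / sub.axis.n_points
    if not floor < target < 1.0:
        raise CalibrationError(
            f"target {target} outside reachable range ({floor:.4f}, 1)"
        )
    lo, hi = -12.0, 12.0  # log10 beta bracket, expanded if needed
    while sub.mean_abs_diag(10.0**lo) < target and lo > -60:
        lo -= 6.0
    while sub.mean_abs_diag(10.0**hi) > target and hi < 60:
        hi += 6.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        val = sub.mean_abs_diag(10.0**mid)
        if abs(val - target) <= tol:
            return 10.0**mid
        if val > target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach |mean diag - {target}| <= {tol} in {max_iter} steps"
    )


def _check_axis(x: Spectrum, sub: LipidSubspace) -> np.ndarray:
    if x.axis != sub.axis:
        raise ValueError("spectrum axis does not match the lipid subspace axis")
    return x.to_freq().data


def lipid_project(x: Spectrum, sub: LipidSubspace) -> Spectrum:
    """(1 - L) x: the lipid-subspace content of x (network input x2)."""
    return Spectrum(sub.project(_check_axis(x, sub)), sub.axis, "freq")


def apply_l2_suppression(x: Spectrum, sub: LipidSubspace) -> Spectrum:
    """L x: the conventional lipid-suppressed spectrum (baseline)."""
    return Spectrum(sub.apply(_check_axis(x, sub)), sub.axis, "freq")


def build_subspace(
    L: np.ndarray,
    axis: SpectralAxis,
    target: float = DIAG_SETPOINT,
    tol: float = 1e-3,
) -> LipidSubspace:
    """Subspace with beta calibrated to the conventional setpoint."""
    sub = LipidSubspace(L, 0.0, axis)
    beta = calibrate_beta(sub, target=target, tol=tol)
    return sub.with_beta(beta)
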