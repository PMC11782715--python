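"""Low-rank denoising and the evaluation metrics on the phantom.

Applies the conventional post-removal step - a rank-40 truncation of
the Casorati (voxel x time) matrix assuming separable spatial and
temporal components - and reports suppression factors and the simple
SNR/FWHM proxies.
"""

import numpy as np

from walinet import (
    AXIS_3D,
    NuisanceParams,
    build_basis,
    build_phantom,
    load_catalog,
    low_rank_denoise,
)
from walinet.lipid_l2 import build_subspace, extract_lipid_basis
from walinet.postproc import RANGE_LIPID, snr_fwhm, suppression_factor

axis = AXIS_3D
systems, rel_conc = load_catalog()
basis = build_basis(systems, axis)
# lipid-only phantom with a visible noise floor
_, vol = build_phantom((24, 24), NuisanceParams(), basis, rel_conc, seed=0,
                       water_on=False, noise_sigma_rel=3e-3)

# conventional lipid suppression, then rank-40 spatiotemporal denoising
freq = vol.to_freq()
sub = build_subspace(extract_lipid_basis(vol, vol.scalp_mask), axis)
suppressed = freq.with_data(sub.apply(freq.casorati().T).T.reshape(freq.data.shape))
denoised = low_rank_denoise(suppressed, rank=40)

factor, _ = suppression_factor(freq, suppressed, vol.brain_mask, RANGE_LIPID)
print(f"brain lipid suppression factor of the L2 operator: {factor:.1f}-fold")

iy, ix = vol.grid_shape[0] // 2, vol.grid_shape[1] // 2  # brain center
snr_raw, _ = snr_fwhm(suppressed.voxel(iy, ix), noise_range_ppm=(7.5, 8.2))
snr_lr, fwhm = snr_fwhm(denoised.voxel(iy, ix), noise_range_ppm=(7.5, 8.2))
print(f"NAA-region SNR of voxel ({iy},{ix}): {snr_raw:.0f} before, "
      f"{snr_lr:.0f} after low-rank denoising; FWHM {fwhm:.3f} ppm")
print("rank truncation pools information across voxels, raising SNR while")
print("the separable model preserves the shared spectral structure.")
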