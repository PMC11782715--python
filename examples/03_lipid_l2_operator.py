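"""Build and calibrate the lipid-L2 suppression operator.

The operator L = (1 + beta L L^H)^-1 is assembled from 50 synthetic
scalp spectra; beta is bisected until the mean absolute diagonal hits
the conventional 0.938 setpoint, the trade-off between lipid
suppression and metabolite preservation.
"""

import numpy as np

from walinet import AXIS_3D, NuisanceParams, build_basis, load_catalog
from walinet.lipid_l2 import LipidSubspace, calibrate_beta
from walinet.nuisance import sample_lipid_spectrum
from walinet.spin_sim import MetaboliteSampleParams, sample_metabolite_spectrum

axis = AXIS_3D
rng = np.random.default_rng(0)
params = NuisanceParams()
L = np.stack([sample_lipid_spectrum(params, axis, rng).data for _ in range(50)], axis=1)

beta = calibrate_beta(L, axis, target=0.938, tol=1e-3)
sub = LipidSubspace(L, beta, axis)
print(f"calibrated beta = {beta:.3g}")
print(f"mean |diag(L)| = {sub.mean_abs_diag():.4f}  (setpoint 0.938)")

# contaminate a metabolite spectrum with a fresh lipid draw
systems, rel_conc = load_catalog()
basis = build_basis(systems, axis)
m = sample_metabolite_spectrum(
    basis, MetaboliteSampleParams(concentrations={n: 0.5 * rel_conc[n] for n in basis.names})
).data
ref = np.abs(m).max()
lipid = sample_lipid_spectrum(params, axis, rng, ref_scale=ref).data
x1 = m + lipid

suppressed = sub.apply(x1)
lip_mask = axis.ppm_mask(0.7, 1.9)
print(f"lipid-range magnitude before: {np.linalg.norm(x1[lip_mask]):.1f}, "
      f"after: {np.linalg.norm(suppressed[lip_mask]):.1f}, "
      f"metabolite-only: {np.linalg.norm(m[lip_mask]):.1f}")
print("the suppressed spectrum approaches the metabolite-only level; the")
print("difference is the lipid component outside the span of the 50 columns")
print("plus the slight metabolite attenuation the 0.938 setpoint admits.")
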