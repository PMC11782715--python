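"""Simulate metabolite spectra from coupled spin systems.

Builds the bundled catalog on the 3D acquisition grid (453 points,
2326 Hz, 7T) and inspects the lactate spin system: the methyl doublet
at 1.31 ppm split by the 6.93 Hz coupling to the methine proton near
4.10 ppm.
"""

import numpy as np

from walinet import AXIS_3D, build_basis, load_catalog
from walinet.axis import SpectralAxis
from walinet.spin_sim import simulate_metabolite_fid

systems, rel_conc = load_catalog()
basis = build_basis(systems, AXIS_3D)
print(f"simulated {len(basis.entries)} metabolites: {', '.join(basis.names)}")

# fine grid to resolve the 6.93 Hz doublet (0.07 Hz per point)
fine = SpectralAxis(n_points=32768, bandwidth_hz=2326.0)
lac = next(s for s in systems if s.name == "Lac")
mag = np.abs(simulate_metabolite_fid(lac, fine).to_freq().data)

peak = fine.ppm[np.argmax(mag)]
print(f"lactate strongest resonance at {peak:.3f} ppm (methyl doublet)")

mask = fine.ppm_mask(1.2, 1.4)
idx = np.flatnonzero(mask)
sub = mag[mask]
local_max = idx[np.flatnonzero((sub[1:-1] > sub[:-2]) & (sub[1:-1] > sub[2:])) + 1]
top2 = local_max[np.argsort(mag[local_max])[-2:]]
split_hz = abs(np.diff(fine.freq_hz[top2]))[0]
print(f"measured doublet splitting {split_hz:.2f} Hz "
      f"(J = 6.93 Hz; the 2.7 Hz natural linewidth shifts the maxima slightly)")

# relative concentrations drive the randomized sampler
print("physiological ratios (NAA = 1):",
      {k: v for k, v in sorted(rel_conc.items()) if k in ("NAA", "Cr", "Cho", "Lac")})
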