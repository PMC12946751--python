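#!/usr/bin/env python
"""Phase-mask synthesis for a multi-target photostimulation pattern.

Builds a 10-spot multiplexed-Gaussian pattern with diffraction-efficiency
compensation, a Gerchberg-Saxton hologram of an extended disk, and compares
their speckle.  Writes results/holography_summary.json.
"""

import json
from pathlib import Path

import numpy as np

from fiberscope.holography import (
    PropagationModel,
    Spot,
    diffraction_efficiency,
    diffraction_efficiency_compensation,
    gerchberg_saxton,
    multiplexed_gaussian_spots,
    reconstruct,
    shape_power_normalization,
    speckle_contrast,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

model = PropagationModel(grid=512, field_um=480.0)
rng = np.random.default_rng(0)
spots = [Spot(x, y, 10.0) for x, y in rng.uniform(-180.0, 180.0, size=(10, 2))]

weights = diffraction_efficiency_compensation(spots, model)
weighted = [
    Spot(s.x, s.y, s.fwhm, weight=np.sqrt(w)) for s, w in zip(spots, weights)
]
mux = multiplexed_gaussian_spots(weighted, model)
rec = reconstruct(mux.mask, mux.incident, model, spots=spots)
delivered = rec.per_target_power * np.array(
    [diffraction_efficiency(s.x, s.y, model) for s in spots]
)
uniformity = float(delivered.max() / delivered.min())

X, Y = model.coords()
disk = ((X**2 + Y**2) <= 25.0).astype(float)
gs = gerchberg_saxton(disk, model, n_iter=50, seed=0)
c_gs = speckle_contrast(reconstruct(gs.mask, None, model).intensity, disk > 0)
mux1 = multiplexed_gaussian_spots([Spot(0.0, 0.0, 10.0)], model)
c_mux = speckle_contrast(
    reconstruct(mux1.mask, mux1.incident, model).intensity, disk > 0
)

# dendrite-like shapes: equal excitation density despite unequal areas
shape_a = np.zeros((40, 40), dtype=bool)
shape_a[5:35, 18:22] = True  # 120 um^2 elongated shape
shape_b = np.zeros((40, 40), dtype=bool)
shape_b[10:30, 10:30] = True  # 400 um^2 blob
powers = shape_power_normalization([shape_a, shape_b], excitation_density=0.1)

summary = {
    "ten_spot_power_uniformity_max_over_min": uniformity,
    "speckle_contrast_multiplexed_spot": float(c_mux),
    "speckle_contrast_gs_disk": float(c_gs),
    "gs_final_rms_error": float(gs.errors[-1]),
    "gs_iterations": int(gs.n_iter),
    "shape_powers_mW_at_0.1mW_per_um2": [float(p) for p in powers],
}
with open(OUT / "holography_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

print("10-spot multiplexed pattern with efficiency compensation:")
print(f"  delivered-power uniformity (max/min): {uniformity:.2f}")
print(
    f"speckle contrast: multiplexed Gaussian spot {c_mux:.3f} vs "
    f"GS holographic disk {c_gs:.3f}"
)
print(
    f"shape-power normalization (0.1 mW/um^2): "
    f"{powers[0]:.0f} mW for 120 um^2, {powers[1]:.0f} mW for 400 um^2"
)
print(
    "Multiplexed Gaussian spots stay smooth where holographic disks carry "
    "speckle; efficiency reweighting keeps delivered power uniform across "
    "the addressable field."
)
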