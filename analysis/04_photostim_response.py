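#!/usr/bin/env python
"""Photostimulation-response classification and distance decay, end to end.

Generates a synthetic all-optical experiment (10 targeted cells among 400,
off-target activation decaying with distance), classifies responses with
the 3-sigma criterion, and recovers the decay constant from 2000 Bernoulli
outcomes.  Writes results/photostim_summary.json and
results/activation_decay.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fiberscope.stim import (
    activation_probability_fit,
    classify_responses,
    distance_to_nearest_spot,
)
from fiberscope.synth import (
    SceneModel,
    generate_activation_outcomes,
    generate_calcium_movie,
    make_schedule,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

K_TRUE = 18.4  # um, off-target decay constant used by the generator

# --- classification on a dense synthetic FOV ------------------------------
rng = np.random.default_rng(0)
pos = rng.uniform(-220.0, 220.0, size=(400, 2))
schedule = make_schedule(np.arange(10), pos[:10])
scene = SceneModel(cell_positions=pos, amplitude=1.0, noise_sd=0.05)
exp = generate_calcium_movie(scene, schedule, k_true=K_TRUE, p0=1.0, seed=1)
res = classify_responses(exp.traces, exp.schedule)
counts = res.counts()
d = distance_to_nearest_spot(exp.traces.cell_positions, schedule.spot_positions)
ntr = res.label == "nT/R"
ntnr = res.label == "nT/nR"

# --- decay-constant recovery at n = 2000 ----------------------------------
dist, responded, truth = generate_activation_outcomes(
    n_cells=2000, k_true=K_TRUE, seed=0
)
fit = activation_probability_fit(dist, responded, bin_width=10.0)
pd.DataFrame(
    {
        "bin_center_um": fit.bin_centers,
        "activation_probability": fit.probabilities,
        "n_cells": fit.counts,
    }
).to_csv(OUT / "activation_decay.csv", index=False)

summary = {
    "class_counts": counts,
    "median_distance_nTR_um": float(np.median(d[ntr])),
    "median_distance_nTnR_um": float(np.median(d[ntnr])),
    "decay_fit": {
        "A": fit.A,
        "k_um": fit.k,
        "k_se_um": fit.k_se,
        "k_true_um": truth.k_true,
    },
}
with open(OUT / "photostim_summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)

print("Response classes (400 cells, 10 targeted):", counts)
print(
    f"nT/R cells sit at median {summary['median_distance_nTR_um']:.0f} um from "
    f"the nearest spot vs {summary['median_distance_nTnR_um']:.0f} um for nT/nR "
    "- off-target activation clusters around the targets."
)
print(
    f"Decay fit on 2000 outcomes: k = {fit.k:.1f} +- {fit.k_se:.1f} um "
    f"(generator truth {K_TRUE} um)"
)
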