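#!/usr/bin/env python
"""Vacuum versus dense environment: the ion-caging contrast.

Runs the isolated disulfide and the dense supercell at F_low and at ten
times F_low (delay 100 fs) and compares the fluence response of the two
environments.  Writes results/vacuum_vs_dense.csv and prints the distance
and displacement ratios with jackknife error estimates.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ioncage.pump_probe import (  # noqa: E402
    FLUENCE,
    ExperimentConfig,
    PulsePair,
    displacement_ratio,
    jackknife_dispersion,
    run_experiment,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

n_dense = int(sys.argv[1]) if len(sys.argv) > 1 else 20
n_vac = 100
exp = ExperimentConfig()
rows = []
obs = {}
for mode, n in (("dense", n_dense), ("vacuum", n_vac)):
    for label, fluence in (("low", FLUENCE["low"]), ("10x", 10 * FLUENCE["low"])):
        o = run_experiment(
            PulsePair(total_fluence=fluence),
            delays=[100.0],
            n_trajectories=n,
            mode=mode,
            seed=1,
            exp=exp,
        )
        obs[mode, label] = o
        err = jackknife_dispersion(o.values[0], 0.75, 100, seed=1)
        rows.append(
            dict(
                mode=mode,
                fluence=label,
                mean=o.mean[0],
                dispersion=o.dispersion[0],
                jackknife=err,
                max=o.values.max(),
                n=n,
            )
        )
        print(
            f"{mode:6s} {label:>3s}: mean = {o.mean[0]:6.2f} Å "
            f"(± {err:.2f} jackknife), max = {o.values.max():6.2f} Å"
        )

pd.DataFrame(rows).to_csv(OUT / "vacuum_vs_dense.csv", index=False)

d_ratio = obs["dense", "10x"].mean[0] / obs["dense", "low"].mean[0]
v_ratio = displacement_ratio(obs["vacuum", "low"], obs["vacuum", "10x"], 100.0)
print(f"\ndense distance ratio (10x / 1x fluence):        {d_ratio:.2f}")
print(f"vacuum relative-displacement ratio (10x / 1x):  {v_ratio:.1f}")
print(
    "Tenfold fluence barely moves the caged, screened bridge in the dense "
    "cell, while the same change multiplies the vacuum displacement many "
    "times over — the environment, not the bare charge, controls the "
    "dissociation."
)
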