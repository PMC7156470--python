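#!/usr/bin/env python
"""Bragg-termination statistics: Wilson B inflation and N(z) distortion.

Applies the cubic-in-time effective B-factor (125 Å² thaumatin-like and
500 Å² heavy-atom-complex-like endpoints over a 100 fs window) to a
Wilson-distributed reference set, fits Wilson plots before and after, and
writes the damage report to results/bragg_report.json plus the N(z)
curves to results/bragg_nz.csv.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ioncage.bragg_termination import (  # noqa: E402
    BraggConfig,
    attenuate,
    bragg_report,
    cumulative_intensity_distribution,
    wilson_fit,
)
from ioncage.synthetic_data import generate_reference_intensities  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

refl = generate_reference_intensities(50_000, wilson_b=20.0, seed=1)
b0, _ = wilson_fit(refl)
print(f"reference set: fitted Wilson B = {b0:.2f} Å² (generated with 20 Å²)")

reports = {}
frames = []
for label, b_end in (("thaumatin_like", 125.0), ("heavy_complex_like", 500.0)):
    cfg = BraggConfig(b_end=b_end, pulse_length=100.0)
    rep = bragg_report(refl, cfg)
    reports[label] = rep
    damped = attenuate(refl, cfg)
    z, emp, ideal = cumulative_intensity_distribution(damped)
    frames.append(
        pd.DataFrame(
            {"case": label, "z": z, "empirical": emp, "ideal_acentric": ideal}
        )
    )
    print(
        f"{label}: B_eff end = {b_end:.0f} Å² -> fitted Wilson B "
        f"{rep['wilson_b_input']:.2f} -> {rep['wilson_b_output']:.2f} Å²"
    )

(OUT / "bragg_report.json").write_text(json.dumps(reports, indent=2) + "\n")
pd.concat(frames).to_csv(OUT / "bragg_nz.csv", index=False)
print(
    "\nSelf-gating damps the high-resolution intensities: the Wilson B "
    "inflates while the resolution-normalized N(z) stays close to the "
    "acentric 1 - exp(-z) law — damage masquerades as extra overall "
    "B-factor, mirroring the time-delay trends seen in the data quality."
)
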