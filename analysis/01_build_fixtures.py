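#!/usr/bin/env python
"""Build and inspect the synthetic fixtures the pipeline runs on.

Writes the 14 Å solvated-protein supercell and the vacuum disulfide to XYZ,
and a Wilson-distributed reference reflection set to CSV, under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ioncage.synthetic_data import (  # noqa: E402
    generate_reference_intensities,
    generate_supercell,
    generate_vacuum_disulfide,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cell = generate_supercell(seed=1)
cell.write_xyz(OUT / "supercell.xyz", comment="14 A solvated-protein supercell")
print(f"supercell: {cell.n_atoms} atoms in a {cell.edge_length} Å cube")
print(f"  composition: {cell.element_counts()}")
print(f"  tracked S-S bridge: {cell.ss_distance():.3f} Å, "
      f"{int(cell.mobile.sum())} atoms inside the {cell.free_radius} Å free sphere")

vac = generate_vacuum_disulfide()
vac.write_xyz(OUT / "vacuum_disulfide.xyz", comment="isolated disulfide moiety")
print(f"vacuum fixture: {vac.n_atoms} atoms, S-S = {vac.ss_distance():.3f} Å, "
      f"centre of mass at origin")

refl = generate_reference_intensities(50_000, wilson_b=20.0, seed=1)
print(f"reference reflections: n={len(refl)}, "
      f"s in [{refl.s.min():.3f}, {refl.s.max():.3f}] Å⁻¹, Wilson B = 20 Å²")
# keep the on-disk artifact small; the full set regenerates from the seed
generate_reference_intensities(1000, wilson_b=20.0, seed=1).to_csv(
    OUT / "reference_intensities.csv"
)
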