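#!/usr/bin/env python
"""Generate every synthetic input used by the downstream analysis stages.

Writes under results/inputs/:
  * phase-solubility diagrams for three host/guest systems at four
    temperatures, with 2e-6 M Gaussian measurement noise (host range 0-10 mM,
    the experimental design of the solubility study);
  * a solvated seven-unit macrocycle trajectory (multi-model PDB) with a
    guest in the cavity;
  * per-snapshot MM/PBSA component tables (100 snapshots x 3 replicates,
    Gaussian around the published component means).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from hostguest import io as hio
from hostguest import phase_thermo as pt
from hostguest import synth

OUT = ROOT / "results" / "inputs"
SEED = 20260927

# ground-truth stability constants used to construct the diagrams: the
# measured Kc(T) table of the three aurisin A / cyclodextrin systems
KC_SERIES = hio.read_kc_csv(ROOT / "data" / "stability_constants.csv")
S0 = 1e-4  # M, intrinsic guest solubility (poorly water-soluble guest)
NOISE_SD = 2e-6  # M, ~1-2% of the measured concentration range


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, series in KC_SERIES.items():
        for i, k in enumerate(series):
            diag = synth.simulate_diagram(
                S0, k.kc, np.linspace(0, 0.010, 11), noise_sd=NOISE_SD,
                seed=SEED + i, temperature=k.temperature, label=label,
            )
            rows.append(pd.DataFrame({
                "host_conc": diag.host_conc, "guest_conc": diag.guest_conc,
                "temperature": diag.temperature, "label": label,
            }))
    sol = pd.concat(rows, ignore_index=True)
    sol.to_csv(OUT / "solubility_diagrams.csv", index=False)
    print(f"wrote {len(sol)} solubility points "
          f"({len(KC_SERIES)} systems x 4 temperatures x 11 host concentrations)")

    cfg = synth.RingConfig(seed=SEED, n_frames=50, jitter_sd=0.12, n_guest=10,
                           n_waters=2000, box=40.0)
    traj, topo = synth.simulate_ring_trajectory(cfg)
    hio.write_pdb_trajectory(traj, topo, OUT / "complex_trajectory.pdb")
    print(f"wrote trajectory: {traj.n_frames} frames, {traj.n_atoms} atoms, "
          f"box {cfg.box} A")

    import json
    ref = json.loads((ROOT / "data" / "mmpbsa_reference.json").read_text())
    means = [ref["means"][c] for c in
             ("e_vdw", "e_ele", "g_solv_polar", "g_solv_nonpolar")]
    tables, entropy = synth.simulate_energy_table(
        means, [1.0] * 4, ref["t_delta_s"], n_snapshots=100, n_replicates=3,
        seed=SEED, t_delta_s_sd=0.25,
    )
    pd.concat(tables, ignore_index=True).to_csv(OUT / "energy_components.csv",
                                                index=False)
    pd.DataFrame({"replicate": [1, 2, 3], "t_delta_s": entropy}).to_csv(
        OUT / "entropy_terms.csv", index=False)
    print("wrote MM/PBSA component tables: 100 snapshots x 3 replicates")


if __name__ == "__main__":
    main()
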