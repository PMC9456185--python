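#!/usr/bin/env python
"""Water accessibility of the simulated complex: RDF and hydration numbers.

Computes the solvent RDF around the guest atoms and around the host O4
(glycosidic) sites over three replicate trajectories, locates the first
g(r) minimum, and tabulates the coordination number n(r) at that minimum,
mean +/- SEM across replicates.  With uniform non-interacting solvent the
expected structure is g ~ 1 beyond contact, so the table mainly demonstrates
the pipeline; buried atoms with no detectable first shell are reported "-".

Writes results/rdf_guest.tsv and results/hydration_table.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from hostguest import io as hio
from hostguest import solvation as sv
from hostguest import synth

SEED = 20260927


def main():
    profiles = {"guest": [], "O4_sites": []}
    for rep in range(3):
        cfg = synth.RingConfig(seed=SEED + rep, n_frames=20, jitter_sd=0.12,
                               n_guest=10, n_waters=2000, box=40.0)
        traj, topo = synth.simulate_ring_trajectory(cfg)
        solvent = topo.indices("solvent")
        profiles["guest"].append(
            sv.rdf(traj, topo.indices("guest"), solvent, dr=0.05, r_max=10.0))
        profiles["O4_sites"].append(
            sv.rdf(traj, topo.site_map["O4"], solvent, dr=0.05, r_max=10.0))

    prof = profiles["guest"][0]
    n_cum = [sv.coordination_number(prof, r).n_of_r for r in prof.r_centers]
    hio.write_report(
        pd.DataFrame({"r_A": prof.r_centers, "g": prof.g_values, "n": n_cum}),
        ROOT / "results" / "rdf_guest.tsv",
    )

    table = sv.hydration_table(profiles, smooth_window=3)
    hio.write_report(table, ROOT / "results" / "hydration_table.tsv")
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    sel = (prof.r_centers >= 2.0) & (prof.r_centers <= 5.0)
    print(f"\nguest-atom RDF plateau over 2-5 A: {prof.g_values[sel].mean():.3f} "
          "(uniform solvent; ~1 expected)")
    print("note: the solvent is uniform and non-interacting, so any detected "
          "'first minimum' reflects shot noise in the sparse small-r shells, "
          "not solvation structure; real trajectories show minima near ~3 A")


if __name__ == "__main__":
    main()
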