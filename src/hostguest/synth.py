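"""Synthetic inputs with known ground truth for every analysis stage.

Each generator produces data with exactly the statistical structure its
analysis stage assumes, so noise-free output is invertible by the analysis
(closure) and noisy output tests estimator behavior at a known truth:

* A_L-type solubility diagrams — guest = S0 + [Kc*S0/(1+Kc*S0)]*host plus
  i.i.d. Gaussian measurement noise;
* Van't Hoff-consistent Kc(T) series — ln Kc exactly linear in 1/T;
* a toy seven-unit macrocycle trajectory with labeled O2/O3/O4 sites, an
  optional guest in the cavity and uniform single-site solvent in a periodic
  box (geometry only: no force field, no bonded terms);
* Gaussian per-snapshot MM/PBSA energy-component tables.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidInputError
from .geometry import Topology, Trajectory
from .phase_thermo import GAS_CONSTANT_KCAL, SolubilityDiagram, StabilityConstant


def al_slope(s0: float, kc: float) -> float:
    """Noise-free A_L diagram slope, Kc*S0 / (1 + Kc*S0)."""
    return kc * s0 / (1.0 + kc * s0)


def simulate_diagram(
    s0: float,
    kc: float,
    host_concs: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
    temperature: float = 303.15,
    label: str = "synthetic",
) -> SolubilityDiagram:
    """A_L-type phase-solubility diagram with Gaussian measurement noise.

    ``guest = S0 + slope*host + N(0, noise_sd)`` with
    ``slope = Kc*S0/(1+Kc*S0)``; noisy guest values are clipped at zero
    (concentrations cannot be negative).
    """
    if not s0 > 0:
        raise DomainError("intrinsic solubility s0 must be positive")
    if kc < 0:
        raise DomainError("stability constant must be non-negative")
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    host = np.asarray(host_concs, dtype=float)
    guest = s0 + al_slope(s0, kc) * host
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        guest = np.clip(guest + rng.normal(0.0, noise_sd, size=host.shape), 0.0, None)
    return SolubilityDiagram(
        host_conc=host, guest_conc=guest, temperature=temperature, label=label
    )


def simulate_vant_hoff(
    delta_h: float,
    delta_s: float,
    temps: Sequence[float],
    noise_sd_logkc: float = 0.0,
    seed: int | None = None,
    gas_constant: float = GAS_CONSTANT_KCAL,
    label: str = "synthetic",
) -> list[StabilityConstant]:
    """Kc(T) series exactly log-linear in 1/T: Kc = exp(-dH/(R*T) + dS/R).

    Optional Gaussian noise is added on ln Kc (multiplicative on Kc), the
    scale on which the Van't Hoff regression operates.
    """
    temps = np.asarray(temps, dtype=float)
    if np.any(temps <= 0):
        raise DomainError("temperatures must be positive (kelvin)")
    log_kc = -delta_h / (gas_constant * temps) + delta_s / gas_constant
    if noise_sd_logkc > 0:
        rng = np.random.default_rng(seed)
        log_kc = log_kc + rng.normal(0.0, noise_sd_logkc, size=temps.shape)
    return [
        StabilityConstant(kc=float(np.exp(lk)), temperature=float(t), label=label)
        for lk, t in zip(log_kc, temps)
    ]


@dataclass(frozen=True)
class RingConfig:
    """Geometry and sampling parameters of the toy macrocycle trajectory.

    Defaults mimic a beta-cyclodextrin-sized ring: seven glucose units,
    glycosidic (O4) ring radius ~5 A, adjacent-rim O3(n)-O2(n+1) separation
    3.0 A (a hydrogen-bondable distance), secondary rim slightly wider and
    above the O4 plane.
    """

    seed: int = 0
    n_frames: int = 10
    n_units: int = 7
    ring_radius: float = 5.0  # A, O4 circumradius
    rim_radius: float = 6.0  # A, O3 circumradius (secondary rim)
    rim_height: float = 2.0  # A, z-offset of the secondary rim
    d32_sep: float = 3.0  # A, exact O3(n)-O2(n+1) separation at zero jitter
    jitter_sd: float = 0.0  # A, per-frame Gaussian displacement of host/guest
    n_guest: int = 0
    guest_radius: float = 1.5  # A, cavity sphere for guest placement
    n_waters: int = 0
    box: float | None = None  # A, cubic box edge (required when n_waters > 0)


def simulate_ring_trajectory(config: RingConfig) -> tuple[Trajectory, Topology]:
    """Toy macrocycle + guest + solvent trajectory with exact site geometry.

    O4 sites sit on a regular n-gon of ``ring_radius`` in the z = 0 plane;
    O3 sites on a wider n-gon at ``rim_height``; each O2(n+1) is placed
    exactly ``d32_sep`` from O3(n) (radially outward), so at zero jitter the
    rim-distance analysis recovers the configured separation identically.
    Host and guest atoms get i.i.d. Gaussian jitter per frame; solvent
    positions are redrawn uniformly in the periodic box every frame.
    """
    cfg = config
    if cfg.n_units < 3:
        raise DomainError("a ring needs at least 3 units")
    if cfg.ring_radius <= 0 or cfg.rim_radius <= 0 or cfg.d32_sep <= 0:
        raise DomainError("ring geometry lengths must be positive")
    if cfg.n_waters > 0:
        if cfg.box is None:
            raise DomainError("solvent requires a box")
        if cfg.box <= 2 * cfg.ring_radius:
            raise DomainError("box must exceed twice the ring radius")
    if cfg.jitter_sd < 0:
        raise DomainError("jitter_sd must be non-negative")

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_units
    theta = 2.0 * math.pi * np.arange(n) / n

    o4 = np.stack(
        [cfg.ring_radius * np.cos(theta), cfg.ring_radius * np.sin(theta), np.zeros(n)],
        axis=1,
    )
    o3 = np.stack(
        [cfg.rim_radius * np.cos(theta), cfg.rim_radius * np.sin(theta),
         np.full(n, cfg.rim_height)],
        axis=1,
    )
    # O2 of unit n+1 placed exactly d32_sep radially outward from O3 of unit n
    radial = np.stack([np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    o2_next = o3 + cfg.d32_sep * radial  # row k is O2 of unit (k % n) + 1
    o2 = np.roll(o2_next, 1, axis=0)  # row k is O2 of unit k+1

    names, elements, roles, units = [], [], [], []
    coords0 = []
    site_map = {"O2": [], "O3": [], "O4": []}
    for u in range(n):
        for site, pos in (("O2", o2[u]), ("O3", o3[u]), ("O4", o4[u])):
            site_map[site].append(len(coords0))
            names.append(site)
            elements.append("O")
            roles.append("host")
            units.append(u + 1)
            coords0.append(pos)

    if cfg.n_guest > 0:
        # uniform in a cavity sphere centred at the ring centre
        vec = rng.normal(size=(cfg.n_guest, 3))
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        rad = cfg.guest_radius * rng.uniform(0, 1, cfg.n_guest) ** (1 / 3)
        gpos = vec * rad[:, None] + np.array([0.0, 0.0, cfg.rim_height / 2])
        for i in range(cfg.n_guest):
            names.append(f"C{i+1}")
            elements.append("C")
            roles.append("guest")
            units.append(0)
            coords0.append(gpos[i])

    n_solute = len(coords0)
    coords0 = np.array(coords0)

    frames = np.empty((cfg.n_frames, n_solute + cfg.n_waters, 3))
    for f in range(cfg.n_frames):
        solute = coords0.copy()
        if cfg.jitter_sd > 0:
            solute = solute + rng.normal(0.0, cfg.jitter_sd, size=solute.shape)
        frames[f, :n_solute] = solute
        if cfg.n_waters > 0:
            frames[f, n_solute:] = rng.uniform(0.0, cfg.box, size=(cfg.n_waters, 3))

    for w in range(cfg.n_waters):
        names.append("OW")
        elements.append("O")
        roles.append("solvent")
        units.append(0)

    topo = Topology(
        names=tuple(names),
        elements=tuple(elements),
        roles=tuple(roles),
        unit_index=np.array(units),
        n_units=n,
        site_map={k: np.array(v) for k, v in site_map.items()},
    )
    box = np.full(3, float(cfg.box)) if cfg.box is not None else None
    traj = Trajectory(
        coordinates=frames,
        box=box,
        frame_stride_note=f"synthetic ring, seed={cfg.seed}",
    )
    return traj, topo


def simulate_energy_table(
    means: Sequence[float],
    sds: Sequence[float],
    t_delta_s: float,
    n_snapshots: int = 100,
    n_replicates: int = 3,
    seed: int | None = None,
    t_delta_s_sd: float = 0.0,
) -> tuple[list[pd.DataFrame], list[float]]:
    """Gaussian per-snapshot MM/PBSA component tables plus per-replicate entropies.

    ``means``/``sds`` are 4-vectors in the order (e_vdw, e_ele, g_solv_polar,
    g_solv_nonpolar), kcal/mol.  Returns one DataFrame per replicate with
    columns replicate, frame and the four components, and one T*dS value per
    replicate (Gaussian around ``t_delta_s`` when ``t_delta_s_sd`` > 0).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if means.shape != (4,) or sds.shape != (4,):
        raise InvalidInputError("means and sds must be 4-vectors")
    if np.any(sds < 0) or t_delta_s_sd < 0:
        raise DomainError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    cols = ("e_vdw", "e_ele", "g_solv_polar", "g_solv_nonpolar")
    tables, entropies = [], []
    for rep in range(1, n_replicates + 1):
        data = means + rng.normal(size=(n_snapshots, 4)) * sds
        df = pd.DataFrame(data, columns=list(cols))
        df.insert(0, "frame", np.arange(1, n_snapshots + 1))
        df.insert(0, "replicate", rep)
        tables.append(df)
        entropies.append(float(t_delta_s + rng.normal() * t_delta_s_sd))
    return tables, entropies
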