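"""Solvent structure around solute atoms: RDF, first minimum, coordination number.

The radial distribution function g(r) counts solvent (water-oxygen) sites in
spherical shells around chosen solute atoms, normalized by the bulk density so
g -> 1 for an unstructured fluid.  The coordination (hydration) number up to a
cutoff is the volume integral

    n(r_cut) = 4 pi rho  int_0^{r_cut} g(r) r^2 dr,

evaluated at the first minimum of g(r) after its first peak it gives the size
of the first solvation shell.  Atoms with no first-solvation peak — those
buried inside the host cavity — are reported as having no hydration number,
mirroring how such entries are tabulated experimentally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidInputError
from .geometry import Trajectory, _pair_distances

DEFAULT_DR = 0.05  # A
DEFAULT_R_MAX = 10.0  # A
DEFAULT_SMOOTH_WINDOW = 3  # bins


@dataclass(frozen=True)
class RDFProfile:
    """Shell-normalized pair distribution g(r) on a uniform radial grid."""

    r_centers: np.ndarray
    g_values: np.ndarray
    bulk_density: float  # particles / A^3
    dr: float
    n_frames: int
    n_centers: int
    raw_counts: np.ndarray | None = None

    def __post_init__(self):
        r = np.asarray(self.r_centers, dtype=float)
        g = np.asarray(self.g_values, dtype=float)
        if r.shape != g.shape or r.ndim != 1:
            raise InvalidInputError("r_centers and g_values must be equal-length 1-D arrays")
        if np.any(g < 0):
            raise InvalidInputError("g(r) must be non-negative")
        if len(r) > 1 and not np.allclose(np.diff(r), self.dr, rtol=1e-6):
            raise InvalidInputError("r_centers must be uniformly spaced by dr")
        object.__setattr__(self, "r_centers", r)
        object.__setattr__(self, "g_values", g)


@dataclass(frozen=True)
class CoordinationResult:
    """Coordination number n(r_cut), with SEM when averaged over replicates."""

    r_cut: float
    n_of_r: float
    sem: float = 0.0


def rdf(
    traj: Trajectory,
    centers: Sequence[int],
    solvent: Sequence[int],
    dr: float = DEFAULT_DR,
    r_max: float = DEFAULT_R_MAX,
    bulk_density: float | None = None,
) -> RDFProfile:
    """Radial distribution function of solvent sites around center atoms.

    Distances use the minimum-image convention when the trajectory carries an
    orthorhombic box; the bulk density then defaults to N_solvent / V_box.
    Without a box an explicit ``bulk_density`` is required.
    """
    if not dr > 0:
        raise InvalidInputError("dr must be positive")
    if not r_max > dr:
        raise InvalidInputError("r_max must exceed dr")
    centers = np.asarray(centers, dtype=int)
    solvent = np.asarray(solvent, dtype=int)
    if centers.size == 0 or solvent.size == 0:
        raise InvalidInputError("centers and solvent selections must be non-empty")
    if bulk_density is None:
        if traj.box is None:
            raise InvalidInputError(
                "rdf needs a periodic box for density normalization, "
                "or an explicit bulk_density"
            )
        bulk_density = solvent.size / float(np.prod(traj.box))
    if not bulk_density > 0:
        raise InvalidInputError("bulk density must be positive")

    n_bins = int(round(r_max / dr))
    edges = dr * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for i in range(traj.n_frames):
        frame = traj.coordinates[i]
        d = _pair_distances(frame[centers], frame[solvent], traj.box).ravel()
        counts += np.histogram(d, bins=edges)[0]

    r_centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * math.pi * r_centers**2 * dr
    g = counts / (shell * bulk_density * traj.n_frames * centers.size)
    return RDFProfile(
        r_centers=r_centers,
        g_values=g,
        bulk_density=float(bulk_density),
        dr=dr,
        n_frames=traj.n_frames,
        n_centers=int(centers.size),
        raw_counts=counts,
    )


def smooth_profile(g: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window of 1 is identity)."""
    if window <= 1:
        return np.asarray(g, dtype=float)
    g = np.asarray(g, dtype=float)
    half = window // 2
    out = np.empty_like(g)
    for i in range(len(g)):
        lo, hi = max(0, i - half), min(len(g), i + half + 1)
        out[i] = g[lo:hi].mean()
    return out


def first_minimum(
    profile: RDFProfile,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> float | None:
    """Radius of the first local minimum of g(r) after its first local maximum.

    Works on a moving-average-smoothed copy of g(r).  Returns ``None`` when no
    maximum-then-minimum pattern exists (monotone or structureless profiles) —
    the caller decides how to report the absence.
    """
    if len(profile.r_centers) < 5:
        raise InvalidInputError("profile needs at least 5 bins for extremum detection")
    g = smooth_profile(profile.g_values, smooth_window)
    r = profile.r_centers
    max_idx = None
    for i in range(1, len(g) - 1):
        if max_idx is None:
            if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] > 0:
                max_idx = i
        else:
            if g[i] < g[i - 1] and g[i] <= g[i + 1]:
                return float(r[i])
    return None


def coordination_number(profile: RDFProfile, r_cut: float) -> CoordinationResult:
    """n(r_cut) = 4 pi rho * integral of g(r) r^2 dr from 0 to r_cut (trapezoid).

    The integrand is anchored at r = 0 (where r^2 g -> 0) and the cutoff bin
    is included by linear interpolation when r_cut falls between bin centers.
    """
    r = profile.r_centers
    if r_cut < 0 or r_cut > r[-1] + profile.dr / 2:
        raise DomainError(f"r_cut {r_cut:.3g} outside the profile range (0, {r[-1]:.3g}]")
    if r_cut == 0:
        return CoordinationResult(r_cut=0.0, n_of_r=0.0)

    integrand = profile.g_values * r**2
    grid = np.concatenate(([0.0], r))
    vals = np.concatenate(([0.0], integrand))
    inside = grid <= r_cut
    gx = grid[inside]
    gy = vals[inside]
    if gx[-1] < r_cut:  # close the interval at exactly r_cut
        y_cut = np.interp(r_cut, grid, vals)
        gx = np.append(gx, r_cut)
        gy = np.append(gy, y_cut)
    n = 4.0 * math.pi * profile.bulk_density * np.trapezoid(gy, gx)
    return CoordinationResult(r_cut=float(r_cut), n_of_r=float(n))


def hydration_table(
    replicate_profiles: Mapping[str, Sequence[RDFProfile]],
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> pd.DataFrame:
    """Per-atom first-shell hydration numbers, mean +/- SEM across replicates.

    For each labeled atom, every replicate's n(r) is evaluated at that
    replicate's own first g(r) minimum.  Atoms whose profiles show no first
    solvation peak in any replicate get ``NaN`` mean/SEM (rendered "-" in
    reports).  SEM uses the sample (n-1) standard deviation over replicates.
    """
    rows = []
    for label, profiles in replicate_profiles.items():
        if len(profiles) == 0:
            raise InvalidInputError(f"atom {label!r} has no replicate profiles")
        n_vals, r_mins = [], []
        for prof in profiles:
            r_min = first_minimum(prof, smooth_window=smooth_window)
            if r_min is not None:
                n_vals.append(coordination_number(prof, r_min).n_of_r)
                r_mins.append(r_min)
        if n_vals:
            n_arr = np.array(n_vals)
            mean = float(n_arr.mean())
            sem = float(n_arr.std(ddof=1) / math.sqrt(len(n_arr))) if len(n_arr) > 1 else 0.0
            r_mean = float(np.mean(r_mins))
        else:
            mean = sem = r_mean = float("nan")
        rows.append(
            {
                "atom": label,
                "r_first_min": r_mean,
                "n_mean": mean,
                "n_sem": sem,
                "n_replicates": len(n_vals),
            }
        )
    return pd.DataFrame(rows)
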