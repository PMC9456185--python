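"""Trajectory descriptors for a macrocyclic host and its bound guest.

Implements the structural observables used to characterize a cyclodextrin
inclusion complex along a simulation: superposed RMSD, radius of gyration,
inter-group atom contacts (native/non-native relative to a reference pose),
the secondary-rim O3(n)-O2(n+1) and glycosidic O4(n)-O4(n+1) distances of the
seven-glucose ring, the fraction of rim distances compatible with an
intramolecular hydrogen bond (d <= 3.5 A), and the Boltzmann-inverted 2-D
free-energy landscape F(x,y) = -kB*T ln P(x,y) over those two distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InvalidInputError,
    TopologyError,
)
from .phase_thermo import GAS_CONSTANT_KCAL

# Standard atomic masses (u) for the elements the toy systems and PDB files use.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.974, "S": 32.06, "F": 18.998, "CL": 35.45,
}

DEFAULT_CONTACT_CUTOFF = 4.5  # A, heavy-atom contact convention
DEFAULT_HBOND_THRESHOLD = 3.5  # A, distance criterion for O3(n)...O2(n+1)
DEFAULT_FEL_BIN = 0.1  # A
DEFAULT_FEL_TEMPERATURE = 303.0  # K


@dataclass(frozen=True)
class Topology:
    """Per-atom roles and the macrocycle's oxygen-site map.

    ``roles`` holds one of ``host``/``guest``/``solvent`` per atom;
    ``unit_index`` is the 1-based glucose-unit id (0 for atoms outside the
    ring).  ``site_map`` maps each of the site names ``O2``, ``O3``, ``O4``
    to an array of atom indices ordered by unit (index u-1 is unit u's site).
    """

    names: tuple[str, ...]
    elements: tuple[str, ...]
    roles: tuple[str, ...]
    unit_index: np.ndarray
    n_units: int
    site_map: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.names)
        if not (len(self.elements) == len(self.roles) == n):
            raise TopologyError("names, elements and roles must have equal length")
        object.__setattr__(self, "unit_index", np.asarray(self.unit_index, dtype=int))
        if self.unit_index.shape != (n,):
            raise TopologyError("unit_index must have one entry per atom")
        if self.n_units > 0:
            for site in ("O2", "O3", "O4"):
                idx = self.site_map.get(site)
                if idx is None or len(idx) != self.n_units:
                    raise TopologyError(
                        f"site_map must provide exactly one {site} per unit "
                        f"({self.n_units} units)"
                    )
        for r in self.roles:
            if r not in ("host", "guest", "solvent"):
                raise TopologyError(f"unknown atom role {r!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def indices(self, role: str) -> np.ndarray:
        """Atom indices with the given role."""
        return np.flatnonzero(np.array(self.roles) == role)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e.upper(), 12.011) for e in self.elements])


@dataclass(frozen=True)
class Trajectory:
    """Cartesian frames (A) with an optional orthorhombic box."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    box: np.ndarray | None = None  # (3,) orthorhombic lengths, A
    frame_stride_note: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InvalidInputError("coordinates must have shape (frames, atoms, 3)")
        object.__setattr__(self, "coordinates", coords)
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape != (3,) or np.any(box <= 0):
                raise InvalidInputError("box must be three positive orthorhombic lengths")
            object.__setattr__(self, "box", box)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class FrameSeries:
    """One scalar observable per frame (RMSD, Rg or contact count)."""

    values: np.ndarray
    kind: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class RimDistances:
    """Adjacent-unit rim distances, frames x n_units, cyclic pairing.

    Column n-1 holds the distance from unit n to unit (n mod n_units)+1, so
    the ring closure pair (n_units -> 1) is always present.
    """

    d32: np.ndarray
    d44: np.ndarray

    def __post_init__(self):
        d32 = np.asarray(self.d32, dtype=float)
        d44 = np.asarray(self.d44, dtype=float)
        if d32.shape != d44.shape or d32.ndim != 2:
            raise InvalidInputError("d32 and d44 must be equal-shape 2-D arrays")
        object.__setattr__(self, "d32", d32)
        object.__setattr__(self, "d44", d44)

    @property
    def n_units(self) -> int:
        return self.d32.shape[1]


@dataclass(frozen=True)
class FELGrid:
    """Binned 2-D free-energy surface from Boltzmann inversion.

    ``f_values`` is a masked array (kcal/mol) shifted so the occupied-cell
    minimum is zero; empty cells are masked.  ``counts`` retains the raw
    histogram so the empirical probabilities can be recovered exactly.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    f_values: np.ma.MaskedArray
    kbt: float
    n_samples: int
    counts: np.ndarray


def _check_selection(coords: np.ndarray, selection) -> np.ndarray:
    if selection is None:
        return coords
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise InvalidInputError("empty atom selection")
    return coords[..., selection, :]


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over the
    selected atoms; the rotation is proper (det = +1) and the RMSD is the
    minimized value.

    Raises
    ------
    DegenerateGeometryError
        If the selected atoms are coincident or collinear, in which case the
        optimal rotation is not unique.
    """
    mob = _check_selection(np.asarray(mobile, dtype=float), selection)
    ref = _check_selection(np.asarray(reference, dtype=float), selection)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise InvalidInputError("mobile and reference selections must be (n, 3) and equal shape")
    if mob.shape[0] < 3:
        raise InvalidInputError("superposition needs at least 3 atoms")

    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    scale = max(np.abs(mob_c).max(), np.abs(ref_c).max(), 1e-300)
    # rank < 2 on either side means collinear or coincident points
    for centered in (mob_c, ref_c):
        sv = np.linalg.svd(centered / scale, compute_uv=False)
        if sv[0] == 0 or np.sum(sv > 1e-8 * sv[0]) < 2:
            raise DegenerateGeometryError("selection is collinear or coincident")

    cov = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    translation = ref.mean(axis=0) - rot @ mob.mean(axis=0)
    diff = mob_c @ rot.T - ref_c
    rmsd = float(np.sqrt((diff**2).sum() / mob.shape[0]))
    return rot, translation, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> FrameSeries:
    """Per-frame RMSD after optimal superposition onto ``reference``."""
    if selection is not None and len(np.asarray(selection)) == 0:
        raise InvalidInputError("empty atom selection")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, values[i] = kabsch_superpose(traj.coordinates[i], reference, selection)
    return FrameSeries(values=values, kind="rmsd")


def rg_series(
    traj: Trajectory,
    selection: Sequence[int] | None = None,
    masses: np.ndarray | None = None,
) -> FrameSeries:
    """Per-frame radius of gyration about the (mass-weighted) centroid.

    With ``masses=None`` all atoms carry unit weight.
    """
    coords = _check_selection(traj.coordinates, selection)
    n_sel = coords.shape[1]
    if n_sel == 0:
        raise InvalidInputError("empty atom selection")
    if masses is None:
        w = np.ones(n_sel)
    else:
        w = np.asarray(masses, dtype=float)
        if w.shape != (n_sel,):
            raise InvalidInputError("masses must match the selection length")
    w = w / w.sum()
    com = np.einsum("fas,a->fs", coords, w)
    sq = ((coords - com[:, None, :]) ** 2).sum(axis=2)
    return FrameSeries(values=np.sqrt(np.einsum("fa,a->f", sq, w)), kind="rg")


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """All inter-group distances, minimum image for orthorhombic boxes."""
    delta = a[:, None, :] - b[None, :, :]
    if box is not None:
        delta -= box * np.round(delta / box)
    return np.sqrt((delta**2).sum(axis=2))


def contact_series(
    traj: Trajectory,
    group_a: Sequence[int],
    group_b: Sequence[int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    reference_frame: int = 0,
) -> tuple[FrameSeries, FrameSeries, FrameSeries]:
    """Inter-group atom contacts per frame: (total, native, nonnative).

    A contact is an (a, b) pair within ``cutoff`` (minimum image when the
    trajectory has a box).  Native contacts are those also present in
    ``reference_frame`` — by default the initial (docked) pose.
    """
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise InvalidInputError("contact groups must be non-empty")
    if np.intersect1d(ga, gb).size:
        raise InvalidInputError("contact groups must be disjoint")
    if not cutoff > 0:
        raise InvalidInputError("cutoff must be positive")

    ref = traj.coordinates[reference_frame]
    ref_mask = _pair_distances(ref[ga], ref[gb], traj.box) <= cutoff
    total = np.empty(traj.n_frames)
    native = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.coordinates[i]
        mask = _pair_distances(frame[ga], frame[gb], traj.box) <= cutoff
        total[i] = mask.sum()
        native[i] = (mask & ref_mask).sum()
    return (
        FrameSeries(total, "contacts_total"),
        FrameSeries(native, "contacts_native"),
        FrameSeries(total - native, "contacts_nonnative"),
    )


def rim_distances(traj: Trajectory, topo: Topology) -> RimDistances:
    """Cyclic adjacent-unit rim distances d32 = |O3(n)-O2(n+1)| and d44 = |O4(n)-O4(n+1)|."""
    for site in ("O2", "O3", "O4"):
        if site not in topo.site_map:
            raise TopologyError(f"site_map is missing {site}")
    o2 = np.asarray(topo.site_map["O2"], dtype=int)
    o3 = np.asarray(topo.site_map["O3"], dtype=int)
    o4 = np.asarray(topo.site_map["O4"], dtype=int)
    nxt = np.roll(np.arange(topo.n_units), -1)  # unit n pairs with n+1, n_units with 1
    c = traj.coordinates
    d32 = np.linalg.norm(c[:, o3, :] - c[:, o2[nxt], :], axis=2)
    d44 = np.linalg.norm(c[:, o4, :] - c[:, o4[nxt], :], axis=2)
    return RimDistances(d32=d32, d44=d44)


def hbond_fraction(rims: RimDistances, threshold: float = DEFAULT_HBOND_THRESHOLD) -> float:
    """Fraction of (frame, unit) rim pairs with d32 <= threshold (possible H-bond)."""
    if not threshold > 0:
        raise InvalidInputError("threshold must be positive")
    return float(np.mean(rims.d32 <= threshold))


def fel_2d(
    x: np.ndarray,
    y: np.ndarray,
    x_bin: float = DEFAULT_FEL_BIN,
    y_bin: float = DEFAULT_FEL_BIN,
    temperature: float = DEFAULT_FEL_TEMPERATURE,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> FELGrid:
    """2-D free-energy landscape by Boltzmann inversion of the sample histogram.

    F(x, y) = -kB*T ln P(x, y), with P the empirical bin probability and
    kB*T the molar R*T in kcal/mol.  F is shifted so the occupied-cell
    minimum is zero; empty cells are masked, not assigned a ceiling.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("samples must be non-empty")
    if x.size != y.size:
        raise InvalidInputError("x and y sample vectors must have equal length")
    if not (x_bin > 0 and y_bin > 0):
        raise InvalidInputError("bin widths must be positive")

    def edges(v, width):
        lo = np.floor(v.min() / width) * width
        n = max(int(np.ceil((v.max() - lo) / width)), 1)
        return lo + width * np.arange(n + 1)

    x_edges = edges(x, x_bin)
    y_edges = edges(y, y_bin)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    kbt = gas_constant * temperature
    prob = counts / x.size
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(prob)
    occupied = counts > 0
    f_masked = np.ma.masked_array(f, mask=~occupied)
    f_masked = f_masked - f_masked.min()
    return FELGrid(
        x_edges=x_edges,
        y_edges=y_edges,
        f_values=f_masked,
        kbt=kbt,
        n_samples=int(x.size),
        counts=counts.astype(int),
    )
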