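"""Aggregation of per-snapshot MM/PBSA energy components into a binding-energy summary.

End-point MM/PBSA estimates a binding free energy from snapshot energies:

    dE_MM   = dE_vdW + dE_ele                (gas-phase molecular mechanics)
    dG_solv = dG_solv,polar + dG_solv,non-polar
    dG_bind = dE_MM + dG_solv - T*dS

The per-snapshot components are inputs here (produced upstream by a
Poisson-Boltzmann/surface-area pipeline); this module derives the combination
terms, averages within replicates and reports cross-replicate mean +/- SEM,
optionally against an experimental dG for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

COMPONENT_COLUMNS = ("e_vdw", "e_ele", "g_solv_polar", "g_solv_nonpolar")
DERIVED_COLUMNS = ("e_mm", "g_solv", "polar_plus_ele", "nonpolar_plus_vdw")

#: Order in which summary terms are reported (matches conventional tables).
TERM_ORDER = (
    "e_vdw", "e_ele", "e_mm",
    "g_solv_polar", "g_solv_nonpolar", "g_solv",
    "polar_plus_ele", "nonpolar_plus_vdw",
    "t_delta_s", "g_bind",
)


@dataclass(frozen=True)
class MMPBSASummary:
    """Cross-replicate mean +/- SEM of every energy term plus the assembled dG_bind.

    ``terms`` maps term name -> (mean, sem) in kcal/mol.  The additivity
    identities (e_mm = e_vdw + e_ele, g_solv = polar + nonpolar,
    g_bind = e_mm + g_solv - t_delta_s) hold exactly on the means.
    """

    terms: dict
    n_replicates: int
    g_exp: float | None = None

    @property
    def g_bind(self) -> float:
        return self.terms["g_bind"][0]

    @property
    def delta_vs_exp(self) -> float | None:
        if self.g_exp is None:
            return None
        return self.g_bind - self.g_exp

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "mean": self.terms[t][0], "sem": self.terms[t][1]}
            for t in TERM_ORDER
        ]
        if self.g_exp is not None:
            rows.append({"term": "g_exp", "mean": self.g_exp, "sem": float("nan")})
        return pd.DataFrame(rows)


def _require_columns(table: pd.DataFrame, columns: Sequence[str]) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SchemaError(f"energy table is missing column(s): {', '.join(missing)}")
    for c in columns:
        if not np.all(np.isfinite(table[c].to_numpy(dtype=float))):
            raise SchemaError(f"non-finite values in column {c!r}")


def derive_terms(table: pd.DataFrame) -> pd.DataFrame:
    """Add the per-snapshot combination columns to an energy-component table.

    Adds ``e_mm``, ``g_solv``, ``polar_plus_ele`` and ``nonpolar_plus_vdw``;
    the input is not modified.
    """
    if len(table) < 1:
        raise InvalidInputError("energy table must have at least one snapshot row")
    _require_columns(table, COMPONENT_COLUMNS)
    out = table.copy()
    out["e_mm"] = out["e_vdw"] + out["e_ele"]
    out["g_solv"] = out["g_solv_polar"] + out["g_solv_nonpolar"]
    out["polar_plus_ele"] = out["g_solv_polar"] + out["e_ele"]
    out["nonpolar_plus_vdw"] = out["g_solv_nonpolar"] + out["e_vdw"]
    return out


def summarize(
    replicates: Sequence[pd.DataFrame],
    entropy: Sequence[float],
    g_exp: float | None = None,
    sem_mode: str = "replicate",
    entropy_per_snapshot: bool = False,
) -> MMPBSASummary:
    """Aggregate replicate energy tables into a mean +/- SEM summary.

    Each replicate table holds per-snapshot components; ``entropy`` supplies
    one T*dS value per replicate (kcal/mol) — entropy estimates are normally
    computed once per replicate, not per snapshot.  With
    ``entropy_per_snapshot=True`` each element of ``entropy`` may instead be a
    sequence of per-snapshot values that is averaged within the replicate.

    ``sem_mode="replicate"`` (default) computes SEM across the replicate
    means, sd/sqrt(n_replicates); ``sem_mode="snapshot"`` pools all snapshots.
    dG_bind is assembled from the mean terms, so the additivity identities
    hold exactly.
    """
    if len(replicates) < 1:
        raise InvalidInputError("need at least one replicate")
    if len(entropy) != len(replicates):
        raise InvalidInputError(
            f"entropy list length {len(entropy)} != replicate count {len(replicates)}"
        )
    if sem_mode not in ("replicate", "snapshot"):
        raise InvalidInputError("sem_mode must be 'replicate' or 'snapshot'")

    extended = [derive_terms(t) for t in replicates]
    t_ds = np.array(
        [float(np.mean(e)) if entropy_per_snapshot else float(e) for e in entropy]
    )

    energy_terms = list(COMPONENT_COLUMNS + DERIVED_COLUMNS)
    # per-replicate means, one row per replicate
    rep_means = pd.DataFrame(
        [{c: t[c].mean() for c in energy_terms} for t in extended]
    )
    rep_means["t_delta_s"] = t_ds
    rep_means["g_bind"] = rep_means["e_mm"] + rep_means["g_solv"] - rep_means["t_delta_s"]

    n_rep = len(replicates)
    terms: dict[str, tuple[float, float]] = {}
    for col in TERM_ORDER:
        vals = rep_means[col].to_numpy()
        mean = float(vals.mean())
        if sem_mode == "replicate" or col in ("t_delta_s", "g_bind"):
            sem = float(vals.std(ddof=1) / math.sqrt(n_rep)) if n_rep > 1 else 0.0
        else:
            pooled = np.concatenate([t[col].to_numpy() for t in extended])
            sem = (
                float(pooled.std(ddof=1) / math.sqrt(len(pooled)))
                if len(pooled) > 1
                else 0.0
            )
        terms[col] = (mean, sem)
    return MMPBSASummary(terms=terms, n_replicates=n_rep, g_exp=g_exp)


def compare_experiment(summary: MMPBSASummary, g_exp: float) -> float:
    """Signed difference dG_bind(computed) - dG_exp in kcal/mol."""
    return summary.g_bind - g_exp
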