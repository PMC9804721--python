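"""CSV writers/readers for branches, envelopes, TPC families and trajectories.

All writers are deterministic (fixed column order, full float precision via
``repr``-round-tripping pandas defaults) so write->read reproduces values
exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .niche_geometry import NicheEnvelope
from .records import Bifurcation, EquilibriumBranch, EquilibriumRecord
from .regime_mapper import RegimeGrid

__all__ = ["branch_frame", "write_branch_csv", "read_branch_csv",
           "write_envelope_csv", "write_regime_csv", "write_trajectory_csv"]

BRANCH_COLUMNS = ["T_C", "branch", "R_hat", "C_hat", "stable", "eig_re_max",
                  "r_T", "K_T", "bif_type"]


def branch_frame(branch: EquilibriumBranch, rates: dict | None = None) -> pd.DataFrame:
    """Tabulate a branch; ``rates`` optionally maps T -> (r_T, K_T) columns.

    Bifurcations get dedicated rows (NaN densities, ``bif_type`` set) so the
    detected temperatures survive the round trip at full precision.
    """
    rows = []
    for rec in branch.records:
        r_T, K_T = (rates.get(rec.T, (np.nan, np.nan)) if rates else (np.nan, np.nan))
        rows.append({"T_C": rec.T, "branch": rec.label, "R_hat": rec.R_hat,
                     "C_hat": rec.C_hat, "stable": rec.stable,
                     "eig_re_max": rec.max_real_eigenvalue,
                     "r_T": r_T, "K_T": K_T, "bif_type": ""})
    for bif in branch.bifurcations:
        rows.append({"T_C": bif.T, "branch": "", "R_hat": np.nan, "C_hat": np.nan,
                     "stable": False, "eig_re_max": np.nan, "r_T": np.nan,
                     "K_T": np.nan, "bif_type": bif.kind})
    df = pd.DataFrame(rows, columns=BRANCH_COLUMNS)
    return df.sort_values(["T_C", "branch"], kind="stable").reset_index(drop=True)


def write_branch_csv(branch: EquilibriumBranch, path, rates: dict | None = None) -> None:
    """Write a branch scan; an empty branch yields a header-only file."""
    branch_frame(branch, rates).to_csv(Path(path), index=False, float_format="%.17g")


def read_branch_csv(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    for col in ("branch", "bif_type"):
        df[col] = df[col].fillna("").astype(str)
    return df


def write_envelope_csv(env: NicheEnvelope, path) -> None:
    """Envelope export: columns (T_C, R, branch_label)."""
    parts = [
        pd.DataFrame({"T_C": env.boundary[:, 0], "R": env.boundary[:, 1],
                      "branch_label": "zngi"}),
        pd.DataFrame({"T_C": env.topt_ridge[:, 1], "R": env.topt_ridge[:, 0],
                      "branch_label": "topt_ridge"}),
        pd.DataFrame({"T_C": [env.collapse_point[0]], "R": [env.collapse_point[1]],
                      "branch_label": "collapse"}),
    ]
    pd.concat(parts, ignore_index=True).to_csv(Path(path), index=False,
                                               float_format="%.17g")


def write_regime_csv(grid: RegimeGrid, path) -> None:
    """Long-format regime grid: columns (delta_T, T_C, label)."""
    grid.to_frame().to_csv(Path(path), index=False, float_format="%.17g")


def write_trajectory_csv(traj, path) -> None:
    """Trajectory export: columns (t, R, C)."""
    pd.DataFrame({"t": traj.times, "R": traj.R, "C": traj.C}).to_csv(
        Path(path), index=False, float_format="%.17g")
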