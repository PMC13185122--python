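"""Lateral diffusion from mean squared displacement of lipid reference atoms.

MSD is computed per species over in-plane (xy) displacements at a set of
strides (1..128 ns in powers of two by default), averaging over every time
origin and every lipid that satisfies the core-membership criterion. The
diffusion coefficient is one quarter of the slope of an ordinary
least-squares line through MSD(tau), the 2D Einstein relation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import floor, log10

import numpy as np
import pandas as pd

from .core import SelectionConfig, Trajectory

DEFAULT_STRIDES = tuple(float(2**k) for k in range(8))  # 1..128 ns


@dataclass
class DiffusionParams:
    strides: tuple[float, ...] = DEFAULT_STRIDES  # ns
    core_radius: float = 40.0  # A; lipids counted in the 4 nm central cylinder
    membership: str = "initial-frame"  # or "both-endpoints"

    def __post_init__(self):
        s = np.asarray(self.strides, dtype=float)
        if len(s) == 0 or np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("strides must be positive and increasing")
        if self.membership not in ("initial-frame", "both-endpoints"):
            raise ValueError("membership must be 'initial-frame' or 'both-endpoints'")


@dataclass
class DiffusionResult:
    species: str
    msd_table: pd.DataFrame  # stride_ns, msd, n_pairs
    D: float  # A^2/ns
    r_squared: float
    intercept: float = field(default=0.0)


def msd(
    traj: Trajectory,
    species: str,
    sel: SelectionConfig,
    params: DiffusionParams | None = None,
) -> pd.DataFrame:
    """In-plane MSD table (stride_ns, msd, n_pairs) for one lipid species.

    All time origins are used. Membership in the core cylinder is evaluated at
    the origin frame (default) or at both endpoints. Strides that do not fit
    in the trajectory span, or that are not a multiple of the frame interval,
    are skipped with a warning.
    """
    params = params or DiffusionParams()
    times = traj.times
    if len(times) < 2:
        raise ValueError("need at least two frames")
    dt = times[1] - times[0]
    if not np.allclose(np.diff(times), dt):
        raise ValueError("MSD requires uniformly spaced frames")
    idx_all, res_all = sel.reference_indices(traj.atoms, roles=("lipid", "detergent"))
    species_of = traj.atoms.residue_species()[res_all]
    idx = idx_all[species_of == species]
    if len(idx) == 0:
        raise ValueError(f"species {species!r} absent")
    pos = np.empty((len(times), len(idx), 2))  # (T, L, 2); gathered per frame
    for i, fr in enumerate(traj.frames):
        pos[i] = fr.coordinates[idx, :2]
    rho = np.linalg.norm(pos, axis=2)
    in_core = rho <= params.core_radius
    span = times[-1] - times[0]
    rows = []
    for tau in params.strides:
        s_float = tau / dt
        s = int(round(s_float))
        if abs(s_float - s) > 1e-6 or s < 1:
            warnings.warn(f"stride {tau} ns is not a multiple of the frame "
                          f"interval {dt} ns; skipped", stacklevel=2)
            continue
        if tau > span + 1e-9:
            warnings.warn(f"stride {tau} ns exceeds the trajectory span; skipped",
                          stacklevel=2)
            continue
        disp = pos[s:] - pos[:-s]
        mask = in_core[:-s]
        if params.membership == "both-endpoints":
            mask = mask & in_core[s:]
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"no valid origin for stride {tau} ns; skipped",
                          stacklevel=2)
            continue
        sq = (disp**2).sum(axis=2)
        rows.append((tau, float(sq[mask].mean()), n))
    if not rows:
        raise ValueError("no stride produced any displacement pair")
    return pd.DataFrame(rows, columns=["stride_ns", "msd", "n_pairs"])


def diffusion_coefficient(msd_table: pd.DataFrame) -> tuple[float, float, float]:
    """OLS fit of MSD vs stride: returns (D, R^2, intercept), D = slope / 4.

    The intercept absorbs any stride-independent offset (e.g. localisation
    noise); a low R^2 flags non-diffusive (ballistic or confined) motion.
    """
    if len(msd_table) < 2:
        raise ValueError("need at least 2 strides to fit a slope")
    x = msd_table["stride_ns"].to_numpy(dtype=float)
    y = msd_table["msd"].to_numpy(dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope) / 4.0, r2, float(intercept)


def diffusion_analysis(
    traj: Trajectory,
    sel: SelectionConfig,
    params: DiffusionParams | None = None,
    species: list[str] | None = None,
) -> list[DiffusionResult]:
    """MSD + D for each (or every present) lipid species."""
    if species is None:
        present = set(traj.atoms.residue_species())
        species = [sp for sp in sel.species_with_role("lipid", "detergent")
                   if sp in present]
    out = []
    for sp in species:
        table = msd(traj, sp, sel, params)
        D, r2, b = diffusion_coefficient(table)
        out.append(DiffusionResult(sp, table, D, r2, b))
    return out


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def expected_displacement(D: float, t: float) -> float:
    """Expected 2D diffusion distance sqrt(4 D t) in A, to 2 significant figures."""
    if D < 0 or t < 0:
        raise ValueError("D and t must be non-negative")
    return round_sig(float(np.sqrt(4.0 * D * t)), 2)
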