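"""Bilayer tilt collective variable: best-fit rotation and swing-twist split.

The rotation that best aligns the bilayer's (subsampled) C2 atoms to a
reference configuration is factored as R = R_tilt * R_spin, where R_spin is a
twist about the bilayer normal (z) and R_tilt a swing about an axis in the xy
plane. The reported observable is the tilt angle (equivalently its cosine);
an optional harmonic restraint energy on cos(tilt) mirrors the restraint used
to keep a simulated nanodisc from tilting into its periodic image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import SelectionConfig, Trajectory


@dataclass
class TiltState:
    spin_angle: float  # degrees, twist about z
    tilt_angle: float  # degrees, swing about an in-plane axis
    cos_tilt: float
    tilt_axis_azimuth: float  # degrees; 0 by convention when tilt == 0

    @property
    def rotation(self) -> Rotation:
        """Recompose R_tilt * R_spin."""
        spin = Rotation.from_rotvec([0.0, 0.0, np.deg2rad(self.spin_angle)])
        az = np.deg2rad(self.tilt_axis_azimuth)
        axis = np.array([np.cos(az), np.sin(az), 0.0])
        tilt = Rotation.from_rotvec(np.deg2rad(self.tilt_angle) * axis)
        return tilt * spin


@dataclass
class TiltRestraint:
    """Harmonic restraint on cos(tilt): E = k/2 (cos_tilt - target)^2."""

    spring_constant: float = 10000.0  # energy per unit cos^2 (kcal/mol in MD use)
    target_cos: float = 1.0

    def __post_init__(self):
        if self.spring_constant < 0:
            raise ValueError("spring_constant must be >= 0")
        if abs(self.target_cos) > 1:
            raise ValueError("|target_cos| must be <= 1")


def best_fit_rotation(current: np.ndarray, reference: np.ndarray) -> Rotation:
    """Least-RMSD proper rotation mapping ``current`` onto ``reference``.

    Centroids are removed internally; the Kabsch/quaternion solution is
    deterministic and always a proper rotation.
    """
    current = np.asarray(current, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if current.shape != reference.shape or current.ndim != 2 or current.shape[1] != 3:
        raise ValueError("point sets must share an (N, 3) shape")
    if current.shape[0] < 3:
        raise ValueError("need at least 3 points")
    a = reference - reference.mean(axis=0)
    b = current - current.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([a, b]), tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point sets")
    rot, _ = Rotation.align_vectors(a, b)
    return rot


def decompose_spin_tilt(rotation: Rotation, normal: np.ndarray | None = None) -> TiltState:
    """Swing-twist factorisation R = R_tilt * R_spin about the given normal (z).

    The twist quaternion is the normalised projection of the rotation
    quaternion onto the normal axis; the swing (tilt) is what remains. At
    tilt -> 0 the azimuth is reported as 0 by convention; a 180-degree swing
    (twist projection vanishing) falls back to a pure-swing branch.
    """
    if normal is None:
        normal = np.array([0.0, 0.0, 1.0])
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    q = rotation.as_quat()  # (x, y, z, w)
    proj = float(q[:3] @ normal)
    w = float(q[3])
    norm = np.hypot(proj, w)
    if norm < 1e-12:
        # 180-degree swing, twist undefined: take twist = identity
        spin = Rotation.identity()
    else:
        spin = Rotation.from_quat(
            np.append(normal * (proj / norm), w / norm)
        )
    swing = rotation * spin.inv()
    spin_vec = spin.as_rotvec()
    spin_angle = float(np.degrees(spin_vec @ normal))
    swing_vec = swing.as_rotvec()
    tilt_rad = float(np.linalg.norm(swing_vec))
    if tilt_rad < 1e-12:
        azimuth = 0.0
        tilt_rad = 0.0
    else:
        axis = swing_vec / tilt_rad
        azimuth = float(np.degrees(np.arctan2(axis[1], axis[0])))
    return TiltState(
        spin_angle=spin_angle,
        tilt_angle=float(np.degrees(tilt_rad)),
        cos_tilt=float(np.cos(tilt_rad)),
        tilt_axis_azimuth=azimuth,
    )


def tilt_series(
    traj: Trajectory,
    sel: SelectionConfig,
    subsample: int = 4,
    reference_frame: int = 0,
) -> pd.DataFrame:
    """Per-frame tilt state of every ``subsample``-th lipid C2 atom.

    The designated frame (first by default) is the alignment reference.
    Returns columns time_ns, cos_tilt, tilt_deg, spin_deg, azimuth_deg.
    """
    idx, _ = sel.reference_indices(traj.atoms, roles=("lipid",))
    idx = idx[::subsample]
    if len(idx) < 3:
        raise ValueError("subsampled C2 set too small to define a rotation")
    ref = traj.frames[reference_frame].coordinates[idx]
    rows = []
    for fr in traj.frames:
        state = decompose_spin_tilt(best_fit_rotation(fr.coordinates[idx], ref))
        rows.append((fr.time, state.cos_tilt, state.tilt_angle,
                     state.spin_angle, state.tilt_axis_azimuth))
    return pd.DataFrame(
        rows, columns=["time_ns", "cos_tilt", "tilt_deg", "spin_deg", "azimuth_deg"]
    )


def restraint_energy(state: TiltState, restraint: TiltRestraint) -> float:
    """Harmonic energy k/2 (cos_tilt - target)^2 of the tilt restraint."""
    return 0.5 * restraint.spring_constant * (state.cos_tilt - restraint.target_cos) ** 2
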