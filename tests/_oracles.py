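"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available —
dense surface integration, all-pairs distance matrices, nested loops —
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def sasa_grid_oracle(
    coords: np.ndarray,
    radii: np.ndarray,
    target: np.ndarray,
    context: np.ndarray,
    probe: float = 2.0,
    n_theta: int = 50,
    n_phi: int = 100,
) -> float:
    """SASA by equal-area latitude-longitude surface integration, brute burial."""
    z = (np.arange(n_theta) + 0.5) / n_theta * 2.0 - 1.0
    phi = (np.arange(n_phi) + 0.5) / n_phi * 2.0 * np.pi
    zz, pp = np.meshgrid(z, phi, indexing="ij")
    rho = np.sqrt(1.0 - zz**2)
    unit = np.stack([rho * np.cos(pp), rho * np.sin(pp), zz], axis=-1).reshape(-1, 3)
    ctx = coords[context]
    ctx_r = radii[context] + probe
    area = 0.0
    for i in target:
        R = radii[i] + probe
        pts = coords[i] + R * unit
        d2 = ((pts[:, None, :] - ctx[None, :, :]) ** 2).sum(-1)
        d2[:, context == i] = np.inf
        frac = (d2 > ctx_r[None, :] ** 2).all(axis=1).mean()
        area += frac * 4.0 * np.pi * R * R
    return float(area)


def contacts_allpairs_oracle(
    coords: np.ndarray, group_a: np.ndarray, group_b: np.ndarray, cutoff: float
) -> int:
    """Contact count from the full distance matrix."""
    return int((cdist(coords[group_a], coords[group_b]) <= cutoff).sum())


def msd_oracle(
    pos: np.ndarray, stride_frames: int, core_radius: float
) -> tuple[float, int]:
    """All-origins in-plane MSD by nested loops; membership at the origin frame.

    ``pos`` is (n_frames, n_lipids, 2). Returns (msd, n_pairs).
    """
    total = 0.0
    n = 0
    n_frames, n_lip = pos.shape[:2]
    for t in range(n_frames - stride_frames):
        for lip in range(n_lip):
            x0, y0 = pos[t, lip]
            if np.hypot(x0, y0) > core_radius:
                continue
            dx = pos[t + stride_frames, lip, 0] - x0
            dy = pos[t + stride_frames, lip, 1] - y0
            total += dx * dx + dy * dy
            n += 1
    return total / n, n


def debounced_flips_oracle(
    labels: np.ndarray, times: np.ndarray, persistence: float
) -> list[tuple[int, str]]:
    """Flip events of one lipid by frame-by-frame scan with explicit look-ahead.

    ``labels`` is boolean (True = upper). An event at frame k requires the new
    label to hold until ``times >= times[k] + persistence`` or trajectory end.
    """
    events = []
    accepted = labels[0]
    n = len(labels)
    k = 1
    while k < n:
        if labels[k] == accepted:
            k += 1
            continue
        j = k
        while j < n and labels[j] == labels[k]:
            j += 1
        held_to_end = j == n
        held_long = times[j - 1] - times[k] >= persistence
        if held_to_end or held_long:
            direction = "lower_to_upper" if labels[k] else "upper_to_lower"
            events.append((k, direction))
            accepted = labels[k]
        k = j
    return events


def block_means_oracle(
    times: np.ndarray, values: np.ndarray, window: float
) -> list[float]:
    """Per-block means by explicit interval membership."""
    t0 = times[0]
    out = []
    k = 0
    while t0 + k * window <= times[-1] + 1e-12:
        lo, hi = t0 + k * window, t0 + (k + 1) * window
        block = [v for t, v in zip(times, values) if lo - 1e-12 <= t < hi - 1e-12]
        if block:
            out.append(float(np.mean(block)))
        k += 1
    return out


def pure_tilt_gridsearch_oracle(
    current: np.ndarray, reference: np.ndarray,
    angle_range: tuple[float, float], angle_step: float = 0.02,
    azimuth_step: float = 2.0,
) -> float:
    """Best pure-tilt angle (deg) by exhaustive grid over angle and axis azimuth."""
    from scipy.spatial.transform import Rotation

    a = reference - reference.mean(axis=0)
    b = current - current.mean(axis=0)
    best = (np.inf, 0.0)
    for azi in np.arange(0.0, 360.0, azimuth_step):
        axis = np.array([np.cos(np.deg2rad(azi)), np.sin(np.deg2rad(azi)), 0.0])
        for ang in np.arange(angle_range[0], angle_range[1] + angle_step / 2,
                             angle_step):
            rot = Rotation.from_rotvec(np.deg2rad(ang) * axis)
            rmsd = float(((rot.apply(b) - a) ** 2).sum())
            if rmsd < best[0]:
                best = (rmsd, ang)
    return best[1]
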