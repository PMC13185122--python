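"""Atom-pair contact counting between lipid and occluder chemical motifs.

Two atoms are in contact when their Euclidean distance is at or below the
cutoff (4 A by default). Counts are exact — a k-d tree only accelerates the
pair enumeration — and the fraction-of-possible-pairs statistic normalises the
interval-mean count by ``N_A * N_B`` over the whole system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Frame, SelectionConfig, Trajectory

#: Default motif pairings mirroring the lipid-vs-PEG contact panels:
#: (lipid motif, occluder role, occluder motif).
DEFAULT_MOTIF_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("tail", "polymer", "methylene"),
    ("choline", "polymer", "oxygen"),
    ("phosphate", "polymer", "oxygen"),
    ("glycerol", "polymer", "linker"),
    ("ester", "polymer", "oxygen"),
)


@dataclass
class ContactParams:
    cutoff: float = 4.0  # A
    motif_pairs: tuple[tuple[str, str, str], ...] = DEFAULT_MOTIF_PAIRS
    interval: tuple[float, float] | None = None  # (t0, t1) ns; None = skip first 25%
    exclude_hydrogen: bool = True

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def count_contacts(
    frame: Frame, group_a: np.ndarray, group_b: np.ndarray, cutoff: float = 4.0
) -> int:
    """Number of (a, b) pairs with distance <= cutoff; groups must be disjoint."""
    group_a = np.asarray(group_a, dtype=np.intp)
    group_b = np.asarray(group_b, dtype=np.intp)
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("contact groups must be disjoint")
    if len(group_a) == 0 or len(group_b) == 0:
        return 0
    ta = cKDTree(frame.coordinates[group_a])
    tb = cKDTree(frame.coordinates[group_b])
    return int(ta.count_neighbors(tb, cutoff))


def motif_contact_report(
    traj: Trajectory,
    sel: SelectionConfig,
    params: ContactParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame contact counts and interval summary for each motif pair.

    Returns ``(series, summary)``: ``series`` has one row per (frame, pair)
    with the contact count; ``summary`` has per pair the interval-mean count,
    the number of possible pairs ``N_A * N_B``, and
    ``pair_fraction = mean / possible``. A motif resolving to an empty atom set
    is reported with ``possible_pairs = 0`` and NaN fraction rather than
    raising.
    """
    params = params or ContactParams()
    times = traj.times
    if params.interval is None:
        t0 = times[0] + 0.25 * (times[-1] - times[0])
        t1 = times[-1]
    else:
        t0, t1 = params.interval
        if t0 < times[0] - 1e-9 or t1 > times[-1] + 1e-9:
            raise ValueError("interval outside trajectory time span")
    xh = params.exclude_hydrogen
    groups = []
    for lipid_motif, occ_role, occ_motif in params.motif_pairs:
        ga = sel.motif_indices(traj.atoms, "lipid", lipid_motif, exclude_hydrogen=xh)
        gb = sel.motif_indices(traj.atoms, occ_role, occ_motif, exclude_hydrogen=xh)
        groups.append((f"{lipid_motif}-{occ_motif}", ga, gb))

    rows = []
    for fr in traj.frames:
        for label, ga, gb in groups:
            n = count_contacts(fr, ga, gb, params.cutoff) if len(ga) and len(gb) else 0
            rows.append((fr.time, label, n))
    series = pd.DataFrame(rows, columns=["time_ns", "pair", "count"])

    in_win = (series["time_ns"] >= t0 - 1e-9) & (series["time_ns"] <= t1 + 1e-9)
    summary_rows = []
    for label, ga, gb in groups:
        possible = int(len(ga)) * int(len(gb))
        sub = series[in_win & (series["pair"] == label)]["count"]
        mean = float(sub.mean()) if len(sub) else np.nan
        frac = mean / possible if possible else np.nan
        summary_rows.append((label, mean, possible, frac))
    summary = pd.DataFrame(
        summary_rows, columns=["pair", "mean_count", "possible_pairs", "pair_fraction"]
    )
    return series, summary
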