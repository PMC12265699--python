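"""Water classification, interior-water counting and water-bridge detection.

Bound water: oxygen within 3.5 Å of any chitosan heavy atom.  Bulk water:
oxygen at least 10 Å from every chitosan heavy atom.  Interior water:
oxygen inside the slab bounded by the center-of-mass y-planes of the two
interior sheets, restricted to those sheets' xz bounding footprint (padded
2 Å).  A water bridge is one water simultaneously hydrogen-bonded to two
chitosan atoms; a water bonded to n partners yields C(n, 2) bridges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import FibrilTopology, Structure, Trajectory
from .hbonds import HBondCriteria, detect_and_classify, minimum_image

__all__ = [
    "WaterAssignment",
    "WaterBridge",
    "assign_waters",
    "interior_water_count",
    "detect_water_bridges",
    "chitosan_water_hbond_table",
    "hydration_series",
]


@dataclass
class WaterAssignment:
    """Per-frame bound/bulk/neither labels keyed by water residue."""

    labels: Dict[str, str]  # water residue key -> {"bound", "bulk", "neither"}

    @property
    def n_bound(self) -> int:
        return sum(1 for v in self.labels.values() if v == "bound")

    @property
    def n_bulk(self) -> int:
        return sum(1 for v in self.labels.values() if v == "bulk")


@dataclass
class WaterBridge:
    frame: int
    water: str  # water residue key
    partners: Tuple[int, int]  # chitosan atom indices
    category: str  # inter_sheet | intra_sheet | intra_chain


def _water_oxygens(frame: Structure) -> Tuple[np.ndarray, np.ndarray]:
    mask = frame.is_water & (frame.element == "O")
    return np.flatnonzero(mask), frame.residue_key()[mask]


def _chitosan_heavy(frame: Structure, topology: FibrilTopology) -> np.ndarray:
    return np.flatnonzero(
        np.isin(frame.chain_id, topology.chains) & frame.heavy & ~frame.is_water
    )


def assign_waters(
    frame: Structure,
    topology: FibrilTopology,
    bound_cutoff: float = 3.5,
    bulk_cutoff: float = 10.0,
) -> WaterAssignment:
    """Classify each water by its oxygen's minimum distance to chitosan.

    ``bound_cutoff`` and ``bulk_cutoff`` may not overlap (bound < bulk).
    """
    if bound_cutoff >= bulk_cutoff:
        raise ValueError("bound cutoff must be smaller than bulk cutoff")
    ox_idx, ox_keys = _water_oxygens(frame)
    if len(ox_idx) == 0:
        raise ValueError("frame contains no waters")
    heavy = _chitosan_heavy(frame, topology)
    box = frame.box
    if box is not None:
        tree = cKDTree(frame.coords[heavy] % box, boxsize=box)
        dmin, _ = tree.query(frame.coords[ox_idx] % box, k=1)
    else:
        tree = cKDTree(frame.coords[heavy])
        dmin, _ = tree.query(frame.coords[ox_idx], k=1)
    labels = {}
    for key, d in zip(ox_keys, dmin):
        if d < bound_cutoff:
            labels[key] = "bound"
        elif d >= bulk_cutoff:
            labels[key] = "bulk"
        else:
            labels[key] = "neither"
    return WaterAssignment(labels=labels)


def interior_slab(
    frame: Structure, topology: FibrilTopology, pad: float = 2.0
) -> Tuple[Tuple[float, float], Tuple[float, float], Tuple[float, float]]:
    """Geometric bounds (y-slab and padded xz footprint) between the interior sheets."""
    s2, s3 = topology.interior_sheets()
    bounds_y = []
    xs, zs = [], []
    for s in (s2, s3):
        mask = np.isin(frame.chain_id, topology.chains_in_sheet(s)) & frame.heavy
        coords = frame.coords[mask]
        bounds_y.append(coords[:, 1].mean())
        xs.append(coords[:, 0])
        zs.append(coords[:, 2])
    ylo, yhi = sorted(bounds_y)
    x = np.concatenate(xs)
    z = np.concatenate(zs)
    return (
        (x.min() - pad, x.max() + pad),
        (ylo, yhi),
        (z.min() - pad, z.max() + pad),
    )


def interior_water_count(
    frame: Structure, topology: FibrilTopology, pad: float = 2.0
) -> int:
    """Number of waters between the two interior sheets (geometric slab).

    Requires >= 4 sheets.  An H-bond based alternative is available through
    :func:`detect_water_bridges` with a sheet-pair restriction.
    """
    (xlo, xhi), (ylo, yhi), (zlo, zhi) = interior_slab(frame, topology, pad=pad)
    ox_idx, _ = _water_oxygens(frame)
    if len(ox_idx) == 0:
        return 0
    o = frame.coords[ox_idx]
    inside = (
        (o[:, 0] >= xlo) & (o[:, 0] <= xhi)
        & (o[:, 1] >= ylo) & (o[:, 1] <= yhi)
        & (o[:, 2] >= zlo) & (o[:, 2] <= zhi)
    )
    return int(inside.sum())


def detect_water_bridges(
    frame: Structure,
    topology: FibrilTopology,
    criteria: HBondCriteria = HBondCriteria(),
    frame_index: int = 0,
    restrict: Optional[Tuple[int, int]] = None,
    same_sheet: Optional[int] = None,
) -> List[WaterBridge]:
    """Waters simultaneously H-bonded (as donor or acceptor) to two chitosan atoms.

    Each unordered partner pair is counted once per water per frame; a water
    with n chitosan partners yields C(n, 2) bridges.  ``restrict=(s, t)``
    keeps only bridges whose partners span sheets s and t; ``same_sheet=s``
    keeps intra-sheet bridges within sheet s.
    """
    events = detect_and_classify(frame, topology, criteria, frame_index=frame_index)
    keys = frame.residue_key()
    partners: Dict[str, set] = {}
    for ev in events:
        if ev.category != "chitosan_water":
            continue
        if frame.is_water[ev.donor]:
            water, chito = keys[ev.donor], ev.acceptor
        else:
            water, chito = keys[ev.acceptor], ev.donor
        partners.setdefault(water, set()).add(int(chito))

    bridges: List[WaterBridge] = []
    for water, atoms in sorted(partners.items()):
        for a, b in combinations(sorted(atoms), 2):
            ca, cb = frame.chain_id[a], frame.chain_id[b]
            sa, sb = topology.chain_to_sheet[ca], topology.chain_to_sheet[cb]
            if ca == cb:
                category = "intra_chain"
            elif sa == sb:
                category = "intra_sheet"
            else:
                category = "inter_sheet"
            if restrict is not None and {sa, sb} != set(restrict):
                continue
            if same_sheet is not None and not (sa == sb == same_sheet and ca != cb):
                continue
            bridges.append(WaterBridge(frame_index, water, (a, b), category))
    return bridges


#: Chitosan atom roles tabulated for chitosan-water H-bonds.
DONOR_ROLES = ("O6H", "O3H", "NH")
ACCEPTOR_ROLES = ("O6", "O3", "O5", "N")
_DONOR_ROLE_OF = {"O6": "O6H", "O3": "O3H", "N": "NH"}


def chitosan_water_hbond_table(
    trajectory: Trajectory,
    topology: FibrilTopology,
    criteria: HBondCriteria = HBondCriteria(),
    interior_only: bool = True,
) -> pd.DataFrame:
    """Mean per-frame chitosan-water H-bond counts by chitosan atom role.

    Rows are keyed by (role, side) where side is "donor" when chitosan
    donates (roles O6H, O3H, NH) and "acceptor" when chitosan accepts
    (roles O6, O3, O5, N).  By default only the chains of the two interior
    sheets are counted; the exterior sheets have a solvent-facing side.
    """
    if interior_only:
        allowed = set(topology.interior_chains())
    else:
        allowed = set(topology.chains)

    totals: Dict[Tuple[str, str], int] = {
        (role, "donor"): 0 for role in DONOR_ROLES
    }
    totals.update({(role, "acceptor"): 0 for role in ACCEPTOR_ROLES})
    n_frames = 0
    for frame in trajectory.frames():
        events = detect_and_classify(frame, topology, criteria, frame_index=n_frames)
        n_frames += 1
        for ev in events:
            if ev.category != "chitosan_water":
                continue
            if frame.is_water[ev.donor]:
                chito = ev.acceptor
                side = "acceptor"
                role = frame.atom_name[chito]
                if role not in ACCEPTOR_ROLES:
                    continue
            else:
                chito = ev.donor
                side = "donor"
                role = _DONOR_ROLE_OF.get(frame.atom_name[chito])
                if role is None:
                    continue
            if frame.chain_id[chito] not in allowed:
                continue
            totals[(role, side)] += 1
    if n_frames == 0:
        raise ValueError("trajectory holds no frames")
    rows = [
        {"role": role, "side": side, "mean_count": count / n_frames}
        for (role, side), count in totals.items()
    ]
    return pd.DataFrame(rows, columns=["role", "side", "mean_count"])


def hydration_series(
    trajectory: Trajectory,
    topology: FibrilTopology,
    criteria: HBondCriteria = HBondCriteria(),
) -> pd.DataFrame:
    """Per-frame hydration observables.

    Columns: frame, n_bound, n_bulk, n_interior, n_bridges_inter,
    n_bridges_intra (bridge counts over all sheet pairs / sheets).
    """
    rows = []
    for i, frame in enumerate(trajectory.frames()):
        try:
            assignment = assign_waters(frame, topology)
            n_bound, n_bulk = assignment.n_bound, assignment.n_bulk
        except ValueError:
            n_bound = n_bulk = 0
        bridges = detect_water_bridges(frame, topology, criteria, frame_index=i)
        rows.append(
            {
                "frame": i,
                "n_bound": n_bound,
                "n_bulk": n_bulk,
                "n_interior": interior_water_count(frame, topology)
                if topology.n_sheets >= 4
                else 0,
                "n_bridges_inter": sum(1 for b in bridges if b.category == "inter_sheet"),
                "n_bridges_intra": sum(1 for b in bridges if b.category == "intra_sheet"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["frame", "n_bound", "n_bulk", "n_interior", "n_bridges_inter", "n_bridges_intra"],
    )
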