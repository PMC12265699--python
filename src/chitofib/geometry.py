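"""Structural observables: convex-hull volume, ΔVolume, end-to-end distance,
RMSF, sheet-stacking distance and sheet-growth dimension."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .core import FibrilTopology, Structure, Trajectory

__all__ = [
    "HullResult",
    "DegenerateGeometryError",
    "convex_hull_volume",
    "delta_volume",
    "end_to_end",
    "rmsf",
    "sheet_stacking_distance",
    "sheet_growth_dimension",
]


class DegenerateGeometryError(ValueError):
    """Raised when points are coplanar/collinear and no 3D hull exists."""


@dataclass
class HullResult:
    volume: float
    simplices: np.ndarray  # (m, 4) vertex index tuples tiling the hull
    vertices: np.ndarray  # indices of hull vertices in the input point set


def convex_hull_volume(points: np.ndarray) -> HullResult:
    """Convex-hull volume of a 3D point cloud via simplex tessellation.

    The hull is computed with Qhull; the volume is evaluated in-package as
    the sum of tetrahedron volumes |det(v1-v0, v2-v0, v3-v0)| / 3! over a
    Delaunay tessellation of the hull vertices, and cross-checked against
    the hull's own volume.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    if points.shape[0] < 4:
        raise DegenerateGeometryError("a 3D hull requires at least 4 points")
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    try:
        hull = ConvexHull(points)
        tess = Delaunay(points[hull.vertices])
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    simplices = hull.vertices[tess.simplices]
    v0 = points[simplices[:, 0]]
    edges = points[simplices[:, 1:]] - v0[:, None, :]
    volume = float(np.abs(np.linalg.det(edges)).sum() / 6.0)
    if not np.isclose(volume, hull.volume, rtol=1e-9, atol=1e-9):
        raise AssertionError(
            f"simplex-sum volume {volume} disagrees with hull volume {hull.volume}"
        )
    return HullResult(volume=volume, simplices=simplices, vertices=hull.vertices)


def _hull_mask(frame: Structure, selection, heavy_only: bool) -> np.ndarray:
    mask = np.ones(frame.n_atoms, dtype=bool) if selection is None else np.asarray(selection)
    if heavy_only:
        mask = mask & frame.heavy
    return mask


def delta_volume(
    trajectory: Trajectory,
    reference: Optional[Structure] = None,
    selection: Optional[np.ndarray] = None,
    heavy_only: bool = True,
) -> pd.DataFrame:
    """Per-frame convex-hull volume and its change against a fixed reference.

    The reference is the supplied structure (e.g. an energy-minimized state)
    or, by default, the first frame of the trajectory.  ``selection`` (boolean
    mask over atoms) restricts the hull, e.g. to the fibril when waters are
    present.  Columns: frame, volume, delta_volume (Å³).
    """
    rows: List[dict] = []
    v0 = None
    if reference is not None:
        v0 = convex_hull_volume(
            reference.coords[_hull_mask(reference, selection, heavy_only)]
        ).volume
    for i, frame in enumerate(trajectory.frames()):
        vol = convex_hull_volume(frame.coords[_hull_mask(frame, selection, heavy_only)]).volume
        if v0 is None:
            v0 = vol
        rows.append({"frame": i, "volume": vol, "delta_volume": vol - v0})
    if not rows:
        raise ValueError("trajectory holds no frames")
    return pd.DataFrame(rows, columns=["frame", "volume", "delta_volume"])


def end_to_end(frame: Structure, chain: str, terminal_atom: str = "O4") -> Tuple[float, float]:
    """Chain end-to-end distance and contour length (Å).

    The end-to-end distance is between the terminal atoms (default O4) of the
    first and last residue of the chain; the contour length is the polyline
    length through the successive terminal atoms, an upper bound on the
    end-to-end distance by the triangle inequality.
    """
    mask = (frame.chain_id == chain) & (frame.atom_name == terminal_atom)
    if not mask.any():
        raise ValueError(f"chain {chain!r} has no {terminal_atom} atoms")
    res = frame.res_index[mask]
    coords = frame.coords[mask][np.argsort(res)]
    res_sorted = np.sort(res)
    if res_sorted[0] == res_sorted[-1]:
        raise ValueError(f"chain {chain!r} has a single residue; end-to-end undefined")
    dist = float(np.linalg.norm(coords[-1] - coords[0]))
    contour = float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())
    return dist, contour


def end_to_end_table(trajectory: Trajectory, topology: FibrilTopology) -> pd.DataFrame:
    """End-to-end distances for every chain and frame."""
    rows = []
    for i, frame in enumerate(trajectory.frames()):
        for cid in topology.chains:
            d, c = end_to_end(frame, cid)
            rows.append({"frame": i, "chain": cid, "end_to_end": d, "contour": c})
    return pd.DataFrame(rows, columns=["frame", "chain", "end_to_end", "contour"])


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Best-fit superposition of ``mobile`` onto ``target`` (both centered sets)."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + target.mean(axis=0)


def rmsf(trajectory: Trajectory, selection: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation after best-fit superposition.

    Frames are superposed onto the unfitted mean structure, the mean is
    recomputed once, and RMSF_i = sqrt(<|r_i - <r_i>|^2>).
    """
    frames = []
    for frame in trajectory.frames():
        coords = frame.coords if selection is None else frame.coords[selection]
        frames.append(coords)
    if len(frames) < 2:
        raise ValueError("RMSF requires at least two frames")
    stack = np.asarray(frames)
    if stack.shape[1] == 0:
        raise ValueError("empty atom selection")
    mean = stack.mean(axis=0)
    fitted = np.asarray([_kabsch(f, mean) for f in stack])
    mean = fitted.mean(axis=0)
    dev = fitted - mean
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def _sheet_middle_com(frame: Structure, topology: FibrilTopology, sheet: int) -> np.ndarray:
    """Center of mass of the middle chain(s) of a sheet (heavy atoms).

    With an odd number of chains per sheet the middle chain is unique; with
    an even number the mean of the two central chains' COMs is used.
    """
    chains = topology.chains_in_sheet(sheet)
    n = len(chains)
    if n % 2 == 1:
        middle = [chains[n // 2]]
    else:
        middle = [chains[n // 2 - 1], chains[n // 2]]
    coms = []
    for cid in middle:
        mask = (frame.chain_id == cid) & frame.heavy
        coms.append(frame.coords[mask].mean(axis=0))
    return np.mean(coms, axis=0)


def sheet_stacking_distance(frame: Structure, topology: FibrilTopology) -> float:
    """Distance between the middle-chain COMs of the two interior sheets (Å)."""
    s2, s3 = topology.interior_sheets()
    return float(
        np.linalg.norm(
            _sheet_middle_com(frame, topology, s3) - _sheet_middle_com(frame, topology, s2)
        )
    )


def sheet_growth_dimension(frame: Structure, topology: FibrilTopology) -> float:
    """Heavy-atom extent of the fibril along the sheet-growth (x) axis (Å)."""
    mask = np.isin(frame.chain_id, topology.chains) & frame.heavy
    x = frame.coords[mask, 0]
    return float(x.max() - x.min())


def geometry_series(
    trajectory: Trajectory,
    topology: FibrilTopology,
    reference: Optional[Structure] = None,
) -> pd.DataFrame:
    """Per-frame fibril volume, ΔVolume, stacking distance and sheet-growth extent."""
    fibril = np.isin(trajectory.atoms.chain_id, topology.chains)
    dv = delta_volume(trajectory, reference=reference, selection=fibril)
    stacking, growth = [], []
    for frame in trajectory.frames():
        stacking.append(sheet_stacking_distance(frame, topology))
        growth.append(sheet_growth_dimension(frame, topology))
    dv["stacking_distance"] = stacking
    dv["sheet_growth_dim"] = growth
    return dv
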