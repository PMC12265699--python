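"""Dipole vectors from partial charges and orientation-angle analysis.

Dipoles are computed as μ = Σ q_i (r_i - r_cog) in e·Å about the set's
center of geometry; for a neutral set the result is origin-independent.
1 e·Å = 4.803 Debye.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._template import TOY_CHARGES
from .core import FibrilTopology, Structure, Trajectory

__all__ = [
    "EA_TO_DEBYE",
    "ChargeTable",
    "toy_charge_table",
    "dipole_vector",
    "chain_dipole_angle",
    "net_fibril_dipole",
    "water_dipole_orientation",
    "orientation_angles",
    "fit_kappa",
]

#: Conversion constant, 1 e·Å in Debye.
EA_TO_DEBYE = 4.803


class ChargeTable:
    """Map (residue name, atom name) -> partial charge (elementary charges)."""

    def __init__(self, charges: Dict[Tuple[str, str], float], neutrality_tol: float = 1e-6):
        self._charges = dict(charges)
        self.neutrality_tol = neutrality_tol

    def __getitem__(self, key: Tuple[str, str]) -> float:
        try:
            return self._charges[key]
        except KeyError:
            raise KeyError(f"no charge for residue {key[0]!r} atom {key[1]!r}") from None

    def resolve(self, structure: Structure) -> np.ndarray:
        """Per-atom charges for a structure; every atom must be resolvable."""
        return np.array(
            [self[(rn, an)] for rn, an in zip(structure.res_name, structure.atom_name)]
        )

    def check_residue_neutrality(self, tol: float = 1e-6) -> None:
        """Every residue type must carry a net charge within ``tol`` of an integer."""
        per_res: Dict[str, float] = {}
        for (resname, _), q in self._charges.items():
            per_res[resname] = per_res.get(resname, 0.0) + q
        for resname, total in per_res.items():
            if abs(total - round(total)) > tol:
                raise ValueError(
                    f"residue {resname!r} net charge {total:+.6f} is not integral"
                )

    @classmethod
    def from_file(cls, path) -> "ChargeTable":
        """Read a plain-text table: ``resname atom_name charge`` per line."""
        charges = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                body = line.split("#", 1)[0].strip()
                if not body:
                    continue
                parts = body.split()
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'resname atom charge'")
                charges[(parts[0], parts[1])] = float(parts[2])
        return cls(charges)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for (resname, atom), q in sorted(self._charges.items()):
                fh.write(f"{resname:6s} {atom:6s} {q:+.4f}\n")


def toy_charge_table() -> ChargeTable:
    """Packaged toy charges: neutral glucosamine residue plus 3-site water."""
    return ChargeTable(dict(TOY_CHARGES))


def dipole_vector(
    coords: np.ndarray,
    charges: np.ndarray,
    assert_neutral: bool = True,
    neutrality_tol: float = 1e-6,
) -> np.ndarray:
    """μ = Σ q_i r_i about the center of geometry, in e·Å.

    Origin independence holds iff Σ q_i = 0, asserted by default.
    """
    coords = np.asarray(coords, dtype=np.float64)
    charges = np.asarray(charges, dtype=np.float64)
    if coords.shape[0] != charges.shape[0]:
        raise ValueError("one charge per atom required")
    net = charges.sum()
    if assert_neutral and abs(net) > neutrality_tol:
        raise ValueError(
            f"atom set carries net charge {net:+.4g}; dipole would be origin-dependent"
        )
    cog = coords.mean(axis=0)
    return ((coords - cog) * charges[:, None]).sum(axis=0)


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length vector has no orientation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def chain_vector(frame: Structure, chain: str) -> np.ndarray:
    """Vector from the COM of residue 2 to the COM of the second-to-last residue."""
    mask = frame.chain_id == chain
    res = frame.res_index[mask]
    coords = frame.coords[mask]
    n_res = res.max()
    if n_res < 19:
        raise ValueError(f"chain {chain!r} has {n_res} residues; >= 19 required")
    lo = coords[res == 2].mean(axis=0)
    hi = coords[res == n_res - 1].mean(axis=0)
    return hi - lo


def chain_dipole_angle(
    frame: Structure, chain: str, charge_table: Optional[ChargeTable] = None
) -> float:
    """Angle (degrees) between the chain dipole and the chain vector."""
    table = charge_table or toy_charge_table()
    sub = frame.select(frame.chain_id == chain)
    mu = dipole_vector(sub.coords, table.resolve(sub))
    return angle_between(mu, chain_vector(frame, chain))


def chain_dipole(
    frame: Structure, chain: str, charge_table: Optional[ChargeTable] = None
) -> np.ndarray:
    table = charge_table or toy_charge_table()
    sub = frame.select(frame.chain_id == chain)
    return dipole_vector(sub.coords, table.resolve(sub))


def net_fibril_dipole(
    frame: Structure,
    topology: FibrilTopology,
    charge_table: Optional[ChargeTable] = None,
) -> np.ndarray:
    """Vector sum of per-chain dipoles over the whole fibril (e·Å)."""
    return np.sum(
        [chain_dipole(frame, cid, charge_table) for cid in topology.chains], axis=0
    )


_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


def _axis_vector(axis) -> np.ndarray:
    if isinstance(axis, str):
        return _AXES[axis.lower()]
    v = np.asarray(axis, dtype=np.float64)
    return v / np.linalg.norm(v)


def water_dipole(frame: Structure, water_key: str, charges: np.ndarray) -> np.ndarray:
    mask = frame.residue_key() == water_key
    return dipole_vector(frame.coords[mask], charges[mask])


def orientation_angles(
    frame: Structure,
    water_keys: Iterable[str],
    axis="z",
    charge_table: Optional[ChargeTable] = None,
) -> np.ndarray:
    """Dipole orientation angles θ (degrees) of selected waters vs an axis."""
    table = charge_table or toy_charge_table()
    charges = table.resolve(frame)
    ax = _axis_vector(axis)
    keys = frame.residue_key()
    out = []
    for key in water_keys:
        mask = keys == key
        mu = dipole_vector(frame.coords[mask], charges[mask])
        out.append(angle_between(mu, ax))
    return np.asarray(out)


def _langevin(kappa: float) -> float:
    return 1.0 / np.tanh(kappa) - 1.0 / kappa


def fit_kappa(angles_deg: np.ndarray) -> float:
    """Maximum-likelihood concentration κ of P(θ) ∝ sinθ·exp(κ cosθ).

    Solves L(κ) = coth κ - 1/κ = <cos θ>; returns 0 for <cos θ> <= 0
    (isotropic or anti-aligned samples).
    """
    mean_cos = float(np.mean(np.cos(np.deg2rad(angles_deg))))
    if mean_cos <= 1e-12:
        return 0.0
    if mean_cos >= 1.0 - 1e-12:
        return np.inf
    return float(brentq(lambda k: _langevin(k) - mean_cos, 1e-8, 1e4))


@dataclass
class OrientationDistribution:
    angles_deg: np.ndarray
    histogram: pd.DataFrame  # columns: theta_mid, density, density_sin_corrected
    kappa_mle: float
    axis_label: str


def water_dipole_orientation(
    trajectory: Trajectory,
    water_selector,
    axis="z",
    charge_table: Optional[ChargeTable] = None,
    bin_width_deg: float = 2.0,
) -> OrientationDistribution:
    """Orientation-angle distribution for a class of waters over a trajectory.

    ``water_selector(frame)`` returns the residue keys of the waters to
    analyse in that frame (e.g. bulk waters from
    :func:`chitofib.hydration.assign_waters`).  The histogram reports both the
    raw angular density and the sinθ-corrected density (uniform for an
    isotropic ensemble); κ is the Langevin maximum-likelihood estimate.
    """
    all_angles = []
    for frame in trajectory.frames():
        keys = water_selector(frame)
        if len(keys):
            all_angles.append(orientation_angles(frame, keys, axis, charge_table))
    if not all_angles:
        raise ValueError("water class is empty over the whole trajectory")
    angles = np.concatenate(all_angles)
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    hist, _ = np.histogram(angles, bins=edges, density=True)
    mids = 0.5 * (edges[:-1] + edges[1:])
    sin_w = np.sin(np.deg2rad(mids))
    hist_df = pd.DataFrame(
        {
            "theta_mid": mids,
            "density": hist,
            "density_sin_corrected": np.where(sin_w > 0, hist / sin_w, 0.0),
        }
    )
    axis_label = axis if isinstance(axis, str) else "custom"
    return OrientationDistribution(
        angles_deg=angles,
        histogram=hist_df,
        kappa_mle=fit_kappa(angles),
        axis_label=axis_label,
    )
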