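"""Crystallographic fibril construction.

Expands an asymmetric unit under orthorhombic screw-axis symmetry, tiles
unit cells and assembles an oriented multi-sheet fibril with a complete
:class:`~chitofib.core.FibrilTopology`.  When no crystal coordinates are
supplied, a packaged idealized glucosamine template is used so the package
builds with no external downloads.

Lattice conventions (declared, not inferred from the crystal structure):
chains within a sheet are one a-translation apart along x, sheets are one
b-translation apart along y, and each chain is a stack of c-translations
along z with a 2_1 screw relating consecutive residues.  Sheets alternate
direction (+1, -1, ...) so adjacent sheets are antiparallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist

from . import _template
from .core import SUGAR_RESNAME, FibrilTopology, Structure, chain_label

__all__ = [
    "UnitCell",
    "AsymmetricUnit",
    "FibrilSpec",
    "P212121_OPERATORS",
    "CHITOSAN_CELL",
    "apply_symmetry",
    "build_fibril",
    "orient_fibril",
    "fibril_axial_span",
    "ClashWarning",
]


class ClashWarning(UserWarning):
    """Emitted when symmetry copies come closer than the clash threshold."""


#: The four affine operators of the orthorhombic three-screw-axis group,
#: as (3x3 rotation with entries in {-1, 0, 1}, fractional translation).
P212121_OPERATORS: Tuple[Tuple[np.ndarray, np.ndarray], ...] = tuple(
    (np.array(r, dtype=np.int64), np.array(t, dtype=np.float64))
    for r, t in [
        ([[1, 0, 0], [0, 1, 0], [0, 0, 1]], [0.0, 0.0, 0.0]),
        ([[1, 0, 0], [0, -1, 0], [0, 0, -1]], [0.5, 0.5, 0.0]),
        ([[-1, 0, 0], [0, 1, 0], [0, 0, -1]], [0.0, 0.5, 0.5]),
        ([[-1, 0, 0], [0, -1, 0], [0, 0, 1]], [0.5, 0.0, 0.5]),
    ]
)


@dataclass
class UnitCell:
    """Orthorhombic unit cell with symmetry operators."""

    a: float
    b: float
    c: float
    space_group_ops: Sequence[Tuple[np.ndarray, np.ndarray]] = field(
        default_factory=lambda: P212121_OPERATORS
    )

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("lattice lengths must be positive")
        self.space_group_ops = tuple(
            (np.asarray(r, dtype=np.int64), np.asarray(t, dtype=np.float64))
            for r, t in self.space_group_ops
        )
        if not self.space_group_ops:
            raise ValueError("at least one symmetry operator is required")
        if not any(
            np.array_equal(r, np.eye(3, dtype=np.int64)) and np.allclose(t % 1.0, 0.0)
            for r, t in self.space_group_ops
        ):
            raise ValueError("identity operator missing from space group")
        self._check_closure()

    def _check_closure(self) -> None:
        """Operators must be closed under composition modulo unit translations."""
        ops = self.space_group_ops
        for r1, t1 in ops:
            for r2, t2 in ops:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                if not any(
                    np.array_equal(r, r3) and np.allclose(t, t3 % 1.0, atol=1e-9)
                    for r3, t3 in ops
                ):
                    raise ValueError(
                        "symmetry operator set is not closed under composition"
                    )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=np.float64)

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=np.float64) * self.lengths


#: Unit cell of anhydrous chitosan (a, b, c in Å).
CHITOSAN_CELL = UnitCell(*_template.DEFAULT_CELL_LENGTHS)


@dataclass
class AsymmetricUnit:
    """Atoms of the asymmetric unit, in fractional coordinates."""

    atom_names: Sequence[str]
    elements: Sequence[str]
    res_indices: Sequence[int]
    frac_coords: np.ndarray

    def __post_init__(self) -> None:
        self.frac_coords = np.asarray(self.frac_coords, dtype=np.float64)
        if len(self.atom_names) == 0:
            raise ValueError("asymmetric unit is empty")
        if self.frac_coords.shape != (len(self.atom_names), 3):
            raise ValueError("frac_coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.frac_coords)):
            raise ValueError("fractional coordinates must be finite")
        seen = set()
        for name, res in zip(self.atom_names, self.res_indices):
            key = (res, name)
            if key in seen:
                raise ValueError(f"duplicate atom name {name!r} in residue {res}")
            seen.add(key)


@dataclass
class FibrilSpec:
    """Sheet/chain/residue counts of the fibril to build."""

    n_sheets: int = 4
    chains_per_sheet: int = 6
    degree_of_polymerization: int = 20
    sugars_per_c_repeat: int = 2

    def __post_init__(self) -> None:
        for name in ("n_sheets", "chains_per_sheet", "degree_of_polymerization", "sugars_per_c_repeat"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.degree_of_polymerization % self.sugars_per_c_repeat:
            raise ValueError(
                "degree_of_polymerization must be a multiple of sugars_per_c_repeat"
            )


def apply_symmetry(
    asym: AsymmetricUnit, cell: UnitCell, clash_distance: float = 1.0
) -> Structure:
    """Expand an asymmetric unit under the cell's symmetry operators.

    Returns all symmetry copies in Cartesian Å (fractional coordinates scaled
    by ``diag(a, b, c)``).  Copies are labelled by operator index via the
    chain id (``S1``, ``S2``, ...).  A :class:`ClashWarning` is emitted if two
    copies approach within ``clash_distance`` Å.
    """
    names, elements, res_idx, chains, frac_all = [], [], [], [], []
    for op_index, (rot, trans) in enumerate(cell.space_group_ops):
        frac = (asym.frac_coords @ rot.T + trans) % 1.0
        frac_all.append(frac)
        names.extend(asym.atom_names)
        elements.extend(asym.elements)
        res_idx.extend(asym.res_indices)
        chains.extend([f"S{op_index + 1}"] * len(asym.atom_names))
    frac_all = np.vstack(frac_all)
    cart = cell.frac_to_cart(frac_all)

    if len(cell.space_group_ops) > 1 and len(cart) > 1:
        n = len(asym.atom_names)
        mind = np.inf
        for i in range(len(cell.space_group_ops)):
            for j in range(i + 1, len(cell.space_group_ops)):
                d = np.linalg.norm(
                    cart[i * n : (i + 1) * n, None, :] - cart[None, j * n : (j + 1) * n, :],
                    axis=-1,
                )
                mind = min(mind, d.min())
        if mind < clash_distance:
            warnings.warn(
                f"symmetry copies approach to {mind:.2f} Å (< {clash_distance} Å)",
                ClashWarning,
            )

    return Structure(
        atom_name=np.array(names),
        element=np.array(elements),
        res_name=np.full(len(names), SUGAR_RESNAME),
        res_index=np.array(res_idx, dtype=np.int64),
        chain_id=np.array(chains),
        coords=cart,
    )


def _residue_template_from_asym(asym: AsymmetricUnit, cell: UnitCell):
    """Derive a single-residue Cartesian template from an asymmetric unit."""
    first = asym.res_indices[0]
    mask = np.array([r == first for r in asym.res_indices])
    names = tuple(np.array(asym.atom_names)[mask])
    coords = cell.frac_to_cart(asym.frac_coords[mask])
    coords = coords - coords.mean(axis=0)
    return names, coords


def _validate_template(names: Sequence[str]) -> None:
    missing = [a for a in _template.REQUIRED_ATOMS if a not in names]
    if missing:
        raise ValueError(f"residue template missing required named atoms: {missing}")


def build_fibril(
    cell: UnitCell = CHITOSAN_CELL,
    template: Optional[AsymmetricUnit] = None,
    spec: Optional[FibrilSpec] = None,
) -> Tuple[Structure, FibrilTopology]:
    """Assemble a fibril of ``spec.n_sheets`` antiparallel sheets.

    Each sheet holds ``spec.chains_per_sheet`` parallel chains one
    a-translation apart along x; sheets are one b-translation apart along y;
    chains stack ``degree_of_polymerization / sugars_per_c_repeat``
    c-translations along z.  Consecutive residues are related by the 2_1
    screw about the chain axis.

    Returns the built :class:`Structure` and its :class:`FibrilTopology`.
    """
    spec = spec or FibrilSpec()
    if template is None:
        res_names, res_coords = _template.TEMPLATE_ATOM_NAMES, _template.TEMPLATE_COORDS
    else:
        res_names, res_coords = _residue_template_from_asym(template, cell)
    _validate_template(res_names)
    elements = [n[0] for n in res_names]
    nat = len(res_names)
    dp = spec.degree_of_polymerization
    half_c = cell.c / spec.sugars_per_c_repeat

    # One chain in its local frame: residues stacked along z with the screw.
    chain_coords = np.empty((dp * nat, 3))
    for r in range(dp):
        coords = np.asarray(res_coords, dtype=float)
        if r % 2 == 1:
            coords = coords * np.array([-1.0, -1.0, 1.0])
        chain_coords[r * nat : (r + 1) * nat] = coords + np.array([0.0, 0.0, r * half_c])

    names_all, elem_all, res_all, chain_all = [], [], [], []
    coords_all = []
    chain_to_sheet, chain_direction = {}, {}
    k = 0
    for s in range(spec.n_sheets):
        direction = 1 if s % 2 == 0 else -1
        for c in range(spec.chains_per_sheet):
            cid = chain_label(k)
            k += 1
            coords = chain_coords.copy()
            if direction == -1:
                # Antiparallel sheet: rotate the chain 180° about the x axis
                # through its heavy-atom centroid (rigid; preserves intra-sheet
                # geometry and keeps heavy-atom COMs aligned across sheets).
                heavy = np.tile(np.array(elements) != "H", dp)
                centroid = coords[heavy].mean(axis=0)
                coords = (coords - centroid) * np.array([1.0, -1.0, -1.0]) + centroid
            coords = coords + np.array([c * cell.a, s * cell.b, 0.0])
            coords_all.append(coords)
            names_all.extend(res_names * dp)
            elem_all.extend(elements * dp)
            res_all.extend(np.repeat(np.arange(1, dp + 1), nat))
            chain_all.extend([cid] * (dp * nat))
            chain_to_sheet[cid] = s + 1
            chain_direction[cid] = direction

    structure = Structure(
        atom_name=np.array(names_all),
        element=np.array(elem_all),
        res_name=np.full(len(names_all), SUGAR_RESNAME),
        res_index=np.array(res_all, dtype=np.int64),
        chain_id=np.array(chain_all),
        coords=np.vstack(coords_all),
    )
    topology = FibrilTopology(
        chain_to_sheet=chain_to_sheet,
        chain_direction=chain_direction,
        n_sheets=spec.n_sheets,
        chains_per_sheet=spec.chains_per_sheet,
        degree_of_polymerization=dp,
    )
    return structure, topology


def fibril_axial_span(
    structure: Structure, topology: FibrilTopology, spec: Optional[FibrilSpec] = None
) -> float:
    """Axial span of the lattice translations along the fibril axis (Å).

    Measured from the built coordinates as the mean z rise between
    symmetry-equivalent atoms two residues apart, times the number of
    c-repeats per chain.
    """
    spec = spec or FibrilSpec(
        n_sheets=topology.n_sheets,
        chains_per_sheet=topology.chains_per_sheet,
        degree_of_polymerization=topology.degree_of_polymerization,
    )
    n_rep = topology.degree_of_polymerization // spec.sugars_per_c_repeat
    cid = topology.chains[0]
    mask = (structure.chain_id == cid) & (structure.atom_name == "C1")
    res = structure.res_index[mask]
    z = structure.coords[mask, 2]
    order = np.argsort(res)
    z = z[order]
    rises = np.abs(z[2:] - z[:-2])
    return float(n_rep * rises.mean())


def _axes_from_topology(structure: Structure, topology: FibrilTopology) -> np.ndarray:
    """Orthonormal (x̂, ŷ, ẑ) axes inferred from chain and sheet geometry."""
    coords = structure.coords
    # z: mean chain axis, sign-corrected by direction flags.
    zvecs = []
    for cid in topology.chains:
        mask = structure.chain_id == cid
        res = structure.res_index[mask]
        sub = coords[mask]
        rmin = res.min()
        # compare residues of equal screw parity so the 2_1 flip cancels
        same_parity = res[(res - rmin) % 2 == 0]
        rhi = same_parity.max()
        lo = sub[res == rmin].mean(axis=0)
        hi = sub[res == rhi].mean(axis=0)
        zvecs.append((hi - lo) * topology.chain_direction[cid])
    zhat = np.mean(zvecs, axis=0)
    nz = np.linalg.norm(zhat)
    if nz < 1e-9:
        raise ValueError("degenerate geometry: chain axis undefined")
    zhat = zhat / nz
    # y: sheet-stacking direction from sheet centers of mass.
    sheet_coms = []
    for s in range(1, topology.n_sheets + 1):
        mask = np.isin(structure.chain_id, topology.chains_in_sheet(s))
        sheet_coms.append(coords[mask].mean(axis=0))
    stacking = sheet_coms[-1] - sheet_coms[0]
    yhat = stacking - np.dot(stacking, zhat) * zhat
    ny = np.linalg.norm(yhat)
    if ny < 1e-9:
        raise ValueError("degenerate geometry: stacking axis undefined")
    yhat = yhat / ny
    xhat = np.cross(yhat, zhat)
    return np.column_stack([xhat, yhat, zhat])


def orient_fibril(structure: Structure, topology: FibrilTopology) -> Structure:
    """Rigid-body rotate the fibril into the canonical axis frame.

    Sheet growth ends up along x, sheet stacking along y and fibril
    elongation along z; pairwise distances are preserved.
    """
    if topology.n_sheets < 2 or topology.chains_per_sheet < 2:
        raise ValueError("orientation requires >= 2 sheets and >= 2 chains per sheet")
    axes = _axes_from_topology(structure, topology)  # columns are x̂, ŷ, ẑ
    centroid = structure.coords.mean(axis=0)
    out = structure.copy()
    out.coords = (structure.coords - centroid) @ axes + centroid
    return out


def max_extent_axes(structure: Structure) -> np.ndarray:
    """Per-axis extents (max - min) of the coordinates."""
    return structure.coords.max(axis=0) - structure.coords.min(axis=0)


def min_interatomic_distance(structure: Structure) -> float:
    """Smallest pairwise distance; O(n^2), intended for small structures."""
    return float(pdist(structure.coords).min())
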