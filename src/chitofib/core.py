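"""Core data model shared by every analysis module.

A :class:`Structure` is a flat table of atoms (names, residues, chains,
Cartesian coordinates in Å, optional partial charges) plus an optional
orthorhombic box.  A :class:`FibrilTopology` records which chain sits in
which sheet and which way it runs along the fibril axis; every hydrogen-bond
classification in the package is driven by it.  Trajectories are ordered
sequences of frames sharing one atom table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional, Sequence

import numpy as np

#: Residue names recognised as water.
WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

#: Default residue name used for the glucosamine sugar unit.
SUGAR_RESNAME = "GCS"


def chain_label(index: int) -> str:
    """Return a chain identifier for a 0-based chain index (A, B, ..., Z, AA, AB, ...)."""
    letters = ""
    index = int(index)
    while True:
        letters = chr(ord("A") + index % 26) + letters
        index = index // 26 - 1
        if index < 0:
            return letters


@dataclass
class Structure:
    """A set of named atoms at one instant.

    Attributes
    ----------
    atom_name, element, res_name : ndarray of str
        Per-atom labels.  ``res_name`` distinguishes sugar residues from water.
    res_index : ndarray of int
        1-based residue number within the owning chain.
    chain_id : ndarray of str
        Chain identifier; water molecules live on their own chains.
    coords : (n, 3) ndarray of float
        Cartesian coordinates in Å.
    charges : (n,) ndarray of float, optional
        Partial charges in elementary-charge units.
    box : (3,) ndarray of float, optional
        Orthorhombic box edge lengths in Å.
    """

    atom_name: np.ndarray
    element: np.ndarray
    res_name: np.ndarray
    res_index: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    charges: Optional[np.ndarray] = None
    box: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.res_name = np.asarray(self.res_name, dtype="U6")
        self.res_index = np.asarray(self.res_index, dtype=np.int64)
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = self.coords.shape[0]
        for name in ("atom_name", "element", "res_name", "res_index", "chain_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match coords ({n})")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=np.float64)
            if self.charges.shape != (n,):
                raise ValueError("charges must supply exactly one value per atom")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
            if np.any(self.box <= 0):
                raise ValueError("box edges must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def is_water(self) -> np.ndarray:
        """Boolean mask of atoms belonging to water residues."""
        return np.isin(self.res_name, sorted(WATER_RESNAMES))

    @property
    def heavy(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return self.element != "H"

    def residue_key(self) -> np.ndarray:
        """Return a per-atom string key identifying the owning residue."""
        return np.char.add(
            np.char.add(self.chain_id, ":"), self.res_index.astype("U8")
        )

    def select(self, mask: np.ndarray) -> "Structure":
        """Return a new Structure restricted to ``mask`` (indices or boolean)."""
        return Structure(
            atom_name=self.atom_name[mask],
            element=self.element[mask],
            res_name=self.res_name[mask],
            res_index=self.res_index[mask],
            chain_id=self.chain_id[mask],
            coords=self.coords[mask],
            charges=None if self.charges is None else self.charges[mask],
            box=None if self.box is None else self.box.copy(),
        )

    def copy(self) -> "Structure":
        return Structure(
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            res_name=self.res_name.copy(),
            res_index=self.res_index.copy(),
            chain_id=self.chain_id.copy(),
            coords=self.coords.copy(),
            charges=None if self.charges is None else self.charges.copy(),
            box=None if self.box is None else self.box.copy(),
        )

    def with_coords(self, coords: np.ndarray, box: Optional[np.ndarray] = None) -> "Structure":
        """Return a frame sharing this atom table but with new coordinates."""
        out = Structure(
            atom_name=self.atom_name,
            element=self.element,
            res_name=self.res_name,
            res_index=self.res_index,
            chain_id=self.chain_id,
            coords=np.asarray(coords, dtype=np.float64),
            charges=self.charges,
            box=self.box if box is None else np.asarray(box, dtype=np.float64),
        )
        return out


@dataclass
class FibrilTopology:
    """Sheet/chain/residue map of a fibril.

    ``chain_to_sheet`` maps chain id to a 1-based sheet index; ``chain_direction``
    maps chain id to +1/-1 along the fibril (z) axis.  Adjacent sheets run
    antiparallel.  Axis roles are fixed: sheet growth along x, sheet stacking
    along y, fibril elongation along z.
    """

    chain_to_sheet: Dict[str, int]
    chain_direction: Dict[str, int]
    n_sheets: int
    chains_per_sheet: int
    degree_of_polymerization: int
    water_chains: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        expected = self.n_sheets * self.chains_per_sheet
        if len(self.chain_to_sheet) != expected:
            raise ValueError(
                f"topology must hold exactly {expected} chains, got {len(self.chain_to_sheet)}"
            )
        if set(self.chain_to_sheet) != set(self.chain_direction):
            raise ValueError("chain_to_sheet and chain_direction must key the same chains")
        for cid, d in self.chain_direction.items():
            if d not in (-1, 1):
                raise ValueError(f"chain {cid}: direction must be +1 or -1")

    @property
    def chains(self) -> list:
        return sorted(self.chain_to_sheet, key=lambda c: (self.chain_to_sheet[c], c))

    def chains_in_sheet(self, sheet: int) -> list:
        return sorted(c for c, s in self.chain_to_sheet.items() if s == sheet)

    def interior_sheets(self) -> tuple:
        """The two interior sheets (requires >= 4 sheets)."""
        if self.n_sheets < 4:
            raise ValueError("interior sheets require a fibril of at least 4 sheets")
        low = self.n_sheets // 2
        return (low, low + 1)

    def interior_chains(self) -> list:
        s2, s3 = self.interior_sheets()
        return self.chains_in_sheet(s2) + self.chains_in_sheet(s3)

    def sheet_of(self, chain: str) -> int:
        return self.chain_to_sheet[chain]

    def to_dict(self) -> dict:
        return {
            "n_sheets": self.n_sheets,
            "chains_per_sheet": self.chains_per_sheet,
            "degree_of_polymerization": self.degree_of_polymerization,
            "chains": {
                cid: {
                    "sheet": self.chain_to_sheet[cid],
                    "direction": self.chain_direction[cid],
                    "residues": self.degree_of_polymerization,
                }
                for cid in self.chains
            },
            "water_chains": list(self.water_chains),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FibrilTopology":
        chains = d["chains"]
        return cls(
            chain_to_sheet={c: int(v["sheet"]) for c, v in chains.items()},
            chain_direction={c: int(v["direction"]) for c, v in chains.items()},
            n_sheets=int(d["n_sheets"]),
            chains_per_sheet=int(d["chains_per_sheet"]),
            degree_of_polymerization=int(d["degree_of_polymerization"]),
            water_chains=tuple(d.get("water_chains", ())),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FibrilTopology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


class Trajectory:
    """Ordered frames sharing one atom table.

    Subclasses provide :meth:`frames`; in-memory trajectories additionally
    expose the raw coordinate array.
    """

    atoms: Structure

    @property
    def n_frames(self) -> int:  # pragma: no cover - abstract
        raise NotImplementedError

    def frames(self) -> Iterator[Structure]:  # pragma: no cover - abstract
        raise NotImplementedError

    def __iter__(self) -> Iterator[Structure]:
        return self.frames()

    def __len__(self) -> int:
        return self.n_frames


class InMemoryTrajectory(Trajectory):
    """Trajectory backed by an (n_frames, n_atoms, 3) coordinate array."""

    def __init__(self, atoms: Structure, coords: np.ndarray, boxes: Optional[np.ndarray] = None):
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[1:] != (atoms.n_atoms, 3):
            raise ValueError(
                f"coords must have shape (n_frames, {atoms.n_atoms}, 3), got {coords.shape}"
            )
        self.atoms = atoms
        self.coords = coords
        if boxes is None:
            self.boxes = None
        else:
            boxes = np.asarray(boxes, dtype=np.float64)
            if boxes.shape != (coords.shape[0], 3):
                raise ValueError("boxes must have shape (n_frames, 3)")
            if np.any(boxes <= 0):
                raise ValueError("box edges must be positive")
            self.boxes = boxes

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        box = None if self.boxes is None else self.boxes[i]
        return self.atoms.with_coords(self.coords[i], box=box)

    def frames(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)
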