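"""Packaged idealized glucosamine residue template.

The template is *not* a crystallographic structure: it is a fixed, clash-free
arrangement of the named heteroatoms (N, O3, O4, O5, O6), ring carbons and
polar hydrogens that

* repeats with the unit-cell c length every two residues (2_1 screw along z),
* places the O3H hydroxyl so that O3'H-O5 hydrogen bonds to the preceding
  residue form naturally (d ~= 2.78 Å, collinear), and
* points the O6H hydroxyl at the amine nitrogen of the next chain in the
  sheet (one a-translation away) so that O6H-N' intra-sheet bonds form
  naturally, while inter-sheet contacts stay out of hydrogen-bond range.

Coordinates are in Å, in a local frame whose z axis is the chain axis.
"""

from __future__ import annotations

import numpy as np

#: Printed unit-cell lengths of the anhydrous chitosan crystal (Å).
DEFAULT_CELL_LENGTHS = (8.129, 8.347, 10.311)

_A, _B, _C = DEFAULT_CELL_LENGTHS
_RING_R = 1.45  # hexagon circumradius of the idealized pyranose ring
_OH_BOND = 0.97
_NH_BOND = 0.97

# Heavy atoms.  Ring order C1-C2-C3-C4-C5-O5; the chain runs +z with the
# glycosidic O4 bridging toward the previous residue (-z side).
_HEAVY = {
    "C1": (0.000, 0.000, _RING_R),
    "C2": (-1.256, 0.000, 0.725),
    "C3": (-1.256, 0.000, -0.725),
    "C4": (0.000, 0.000, -_RING_R),
    "C5": (1.256, 0.000, -0.725),
    "O5": (1.256, 0.000, 0.725),
    "C6": (2.500, 0.200, -1.500),
    "N": (-2.450, 0.000, 1.300),
    "O3": (-2.400, 0.000, -1.900),
    "O4": (0.000, 0.000, -_C / 4.0),
    "O6": (2.800, 0.300, 0.700),
}


def _screw(p: np.ndarray) -> np.ndarray:
    """2_1 screw component: rotate 180° about the chain (z) axis."""
    return p * np.array([-1.0, -1.0, 1.0])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _build_template() -> tuple:
    heavy = {k: np.asarray(v, dtype=float) for k, v in _HEAVY.items()}

    # HO3 points at O5 of the preceding residue (screwed copy shifted -c/2).
    o5_prev = _screw(heavy["O5"]) + np.array([0.0, 0.0, -_C / 2.0])
    ho3 = heavy["O3"] + _OH_BOND * _unit(o5_prev - heavy["O3"])

    # HO6 points at N of the next chain in the sheet (+a along x).
    n_next_chain = heavy["N"] + np.array([_A, 0.0, 0.0])
    ho6 = heavy["O6"] + _OH_BOND * _unit(n_next_chain - heavy["O6"])

    # HN points toward the stacking direction; it has no natural partner in
    # the ideal lattice (inter-sheet bonds are planted, never built in).
    hn = heavy["N"] + np.array([0.0, _NH_BOND, 0.0])

    names = list(heavy) + ["HN", "HO3", "HO6"]
    coords = np.vstack([heavy[k] for k in heavy] + [hn, ho3, ho6])
    return tuple(names), coords


TEMPLATE_ATOM_NAMES, TEMPLATE_COORDS = _build_template()

#: Atom names the builder requires of any residue template.
REQUIRED_ATOMS = ("N", "O3", "O4", "O5", "O6", "HN", "HO3", "HO6")

#: Hydrogen -> parent heavy atom, within a sugar residue.
SUGAR_H_PARENT = {"HN": "N", "HN2": "N", "HO3": "O3", "HO6": "O6"}

#: Toy partial charges (elementary charge units); each residue is neutral.
TOY_CHARGES = {
    ("GCS", "C1"): 0.10,
    ("GCS", "C2"): 0.10,
    ("GCS", "C3"): 0.10,
    ("GCS", "C4"): 0.10,
    ("GCS", "C5"): 0.10,
    ("GCS", "C6"): 0.10,
    ("GCS", "O3"): -0.40,
    ("GCS", "O4"): -0.30,
    ("GCS", "O5"): -0.30,
    ("GCS", "O6"): -0.40,
    ("GCS", "N"): -0.30,
    ("GCS", "HN"): 0.30,
    ("GCS", "HO3"): 0.40,
    ("GCS", "HO6"): 0.40,
    ("HOH", "O"): -0.834,
    ("HOH", "H1"): 0.417,
    ("HOH", "H2"): 0.417,
}

#: 3-site water geometry: O-H bond length and H-O-H angle.
WATER_OH = 0.9572
WATER_ANGLE_DEG = 104.52
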