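"""Hydrogen-bond detection, topological classification and occupancy.

A hydrogen bond is declared for a (donor, H, acceptor) triple when the
donor-acceptor heavy-atom distance is below the cutoff (default 3.5 Å) and
the donor-H-acceptor angle, measured at the hydrogen, exceeds the angular
cutoff (default 135°).  Minimum-image distances are used when the frame
carries an orthorhombic box.

Each chitosan-chitosan event is classified as exactly one of intra_chain,
intra_sheet or inter_sheet from the fibril topology; events with one water
partner are chitosan_water, with two, water_water.  Named pairs such as
"O3′H–O5" follow a configurable rule table in which the prime marks the
neighbouring residue or chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._template import SUGAR_H_PARENT
from .core import FibrilTopology, Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondEvent",
    "HBondRule",
    "DEFAULT_RULES",
    "detect_hbonds",
    "classify_hbond",
    "classify_events",
    "occupancy",
    "fraction_of_max",
    "inter_chain_count",
    "CATEGORIES",
]

CATEGORIES = ("intra_chain", "intra_sheet", "inter_sheet", "chitosan_water", "water_water")

#: Water hydrogen names mapped to their oxygen.
_WATER_H_PARENT = {"H1": "O", "H2": "O", "HW1": "O", "HW2": "O"}

#: Chitosan heavy atoms that can accept a hydrogen bond.
_SUGAR_ACCEPTORS = {"N", "O3", "O4", "O5", "O6"}


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion."""

    max_distance: float = 3.5  # donor-acceptor heavy-atom distance, Å
    min_angle: float = 135.0  # donor-H-acceptor angle at the hydrogen, degrees

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not (0.0 < self.min_angle <= 180.0):
            raise ValueError("min_angle must lie in (0, 180]")


@dataclass
class HBondEvent:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    category: Optional[str] = None
    named_pair: Optional[str] = None

    def triple(self) -> Tuple[int, int, int]:
        return (self.donor, self.hydrogen, self.acceptor)


@dataclass(frozen=True)
class HBondRule:
    """Maps (donor atom name, acceptor atom name, category) to a pair label.

    ``donor_offset`` applies to intra_chain rules only: the donor residue
    index minus the acceptor residue index required for the label.
    """

    donor: str
    acceptor: str
    category: str
    label: str
    donor_offset: Optional[int] = None


#: Default prime-notation rule table.
DEFAULT_RULES: Tuple[HBondRule, ...] = (
    HBondRule("O3", "O5", "intra_chain", "O3′H–O5", donor_offset=1),
    HBondRule("O6", "O3", "intra_chain", "O6H–O3′", donor_offset=-1),
    HBondRule("N", "O6", "intra_sheet", "N′H–O6"),
    HBondRule("O6", "N", "intra_sheet", "O6H–N′"),
    HBondRule("N", "O4", "inter_sheet", "N′H–O4"),
)


def minimum_image(disp: np.ndarray, box: Optional[np.ndarray]) -> np.ndarray:
    """Apply the minimum-image convention (orthorhombic boxes only)."""
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def donor_table(structure: Structure) -> List[Tuple[int, List[int]]]:
    """Enumerate donor heavy atoms with their covalently assigned hydrogens.

    Assignment is by naming convention within the residue (HO3 -> O3,
    HO6 -> O6, HN -> N; water H1/H2 -> O).  A donor heavy atom present
    without any hydrogen raises ``ValueError``.
    """
    water = structure.is_water
    keys = structure.residue_key()
    # residue key -> {atom name -> atom index}
    by_res: Dict[str, Dict[str, int]] = {}
    for i, key in enumerate(keys):
        by_res.setdefault(key, {})[structure.atom_name[i]] = i

    donors: Dict[int, List[int]] = {}
    for i in range(structure.n_atoms):
        name = structure.atom_name[i]
        parent_map = _WATER_H_PARENT if water[i] else SUGAR_H_PARENT
        if name in parent_map:
            res_atoms = by_res[keys[i]]
            parent_name = parent_map[name]
            if parent_name not in res_atoms:
                raise ValueError(
                    f"hydrogen {name} in residue {keys[i]} has no parent {parent_name}"
                )
            donors.setdefault(res_atoms[parent_name], []).append(i)

    # Any donor-capable heavy atom with no hydrogen at all is an input error
    # only for water (a water O must carry two H); sugar hydroxyls missing an
    # H simply cannot donate.
    for i in np.flatnonzero(water & (structure.atom_name == "O")):
        if len(donors.get(i, ())) != 2:
            raise ValueError(f"water oxygen at index {i} does not carry two hydrogens")
    return sorted(donors.items())


def acceptor_indices(structure: Structure) -> np.ndarray:
    """Indices of hydrogen-bond acceptor heavy atoms (sugar N/O and water O)."""
    water = structure.is_water
    sugar_ok = np.isin(structure.atom_name, sorted(_SUGAR_ACCEPTORS)) & ~water
    water_ok = water & (structure.element == "O")
    return np.flatnonzero(sugar_ok | water_ok)


def detect_hbonds(
    frame: Structure,
    criteria: HBondCriteria = HBondCriteria(),
    frame_index: int = 0,
    exclude_same_residue: bool = True,
) -> List[HBondEvent]:
    """Return every (donor, H, acceptor) triple satisfying the criterion.

    The angle is measured at the hydrogen; distances honour the minimum-image
    convention when the frame has an orthorhombic box.
    """
    donors = donor_table(frame)
    acceptors = acceptor_indices(frame)
    if not donors or len(acceptors) == 0:
        return []
    box = frame.box
    coords = frame.coords
    acc_coords = coords[acceptors]
    if box is not None:
        tree = cKDTree(acc_coords % box, boxsize=box)
    else:
        tree = cKDTree(acc_coords)

    keys = frame.residue_key()
    cos_min = np.cos(np.deg2rad(criteria.min_angle))
    events: List[HBondEvent] = []
    for donor, hydrogens in donors:
        dpos = coords[donor]
        query = dpos % box if box is not None else dpos
        for j in tree.query_ball_point(query, criteria.max_distance):
            acc = int(acceptors[j])
            if acc == donor:
                continue
            if exclude_same_residue and keys[acc] == keys[donor]:
                continue
            dvec = minimum_image(coords[acc] - dpos, box)
            if np.dot(dvec, dvec) >= criteria.max_distance**2:
                continue
            for h in hydrogens:
                hd = minimum_image(dpos - coords[h], box)
                ha = minimum_image(coords[acc] - coords[h], box)
                denom = np.linalg.norm(hd) * np.linalg.norm(ha)
                if denom == 0:
                    continue
                cosang = np.dot(hd, ha) / denom
                # angle > min_angle  <=>  cos(angle) < cos(min_angle)
                if cosang < cos_min:
                    events.append(HBondEvent(frame_index, donor, h, acc))
    return events


def _parent(structure: Structure, topology: FibrilTopology, index: int):
    """Resolve an atom to ('water', None) or ('chitosan', (chain, sheet))."""
    if structure.is_water[index]:
        return "water", None
    cid = structure.chain_id[index]
    if cid not in topology.chain_to_sheet:
        raise ValueError(f"atom {index} (chain {cid!r}) is neither water nor in the topology")
    return "chitosan", (cid, topology.chain_to_sheet[cid])


def classify_hbond(
    event: HBondEvent,
    structure: Structure,
    topology: FibrilTopology,
    rules: Sequence[HBondRule] = DEFAULT_RULES,
) -> HBondEvent:
    """Assign category and named pair to an event in place (and return it)."""
    dkind, dparent = _parent(structure, topology, event.donor)
    akind, aparent = _parent(structure, topology, event.acceptor)

    if dkind == "water" and akind == "water":
        event.category = "water_water"
    elif dkind == "water" or akind == "water":
        event.category = "chitosan_water"
    else:
        dchain, dsheet = dparent
        achain, asheet = aparent
        if dchain == achain:
            event.category = "intra_chain"
        elif dsheet == asheet:
            event.category = "intra_sheet"
        else:
            event.category = "inter_sheet"

    event.named_pair = "other"
    if event.category in ("intra_chain", "intra_sheet", "inter_sheet"):
        dname = structure.atom_name[event.donor]
        aname = structure.atom_name[event.acceptor]
        for rule in rules:
            if rule.category != event.category or rule.donor != dname or rule.acceptor != aname:
                continue
            if rule.donor_offset is not None:
                offset = int(structure.res_index[event.donor] - structure.res_index[event.acceptor])
                if offset != rule.donor_offset:
                    continue
            event.named_pair = rule.label
            break
    return event


def classify_events(
    events: Sequence[HBondEvent],
    structure: Structure,
    topology: FibrilTopology,
    rules: Sequence[HBondRule] = DEFAULT_RULES,
) -> List[HBondEvent]:
    return [classify_hbond(e, structure, topology, rules) for e in events]


def detect_and_classify(
    frame: Structure,
    topology: FibrilTopology,
    criteria: HBondCriteria = HBondCriteria(),
    frame_index: int = 0,
    rules: Sequence[HBondRule] = DEFAULT_RULES,
) -> List[HBondEvent]:
    return classify_events(
        detect_hbonds(frame, criteria, frame_index=frame_index), frame, topology, rules
    )


def occupancy(
    trajectory: Trajectory,
    topology: FibrilTopology,
    pairs: Optional[Sequence] = None,
    criteria: HBondCriteria = HBondCriteria(),
    rules: Sequence[HBondRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Per-pair-type occupancy table over a trajectory.

    ``pairs`` selects (named_pair, category) rows (labels alone also work);
    ``None`` reports every labelled pair observed.  The occupancy of a row is
    the mean, over the symmetry-equivalent (donor, acceptor) instances seen
    at least once, of the fraction of frames in which that instance is
    bonded.  Columns: pair, category, occupancy, mean_count, n_instances,
    n_frames.
    """
    if pairs is not None:
        wanted = set()
        for p in pairs:
            wanted.add(p if isinstance(p, tuple) else (p, None))
    else:
        wanted = None

    counts: Dict[Tuple[str, str], Dict[Tuple[int, int], int]] = {}
    per_frame_total: Dict[Tuple[str, str], int] = {}
    n_frames = 0
    for frame in trajectory.frames():
        events = detect_and_classify(frame, topology, criteria, frame_index=n_frames, rules=rules)
        n_frames += 1
        seen_this_frame = set()
        for ev in events:
            if ev.named_pair == "other":
                continue
            key = (ev.named_pair, ev.category)
            inst = (ev.donor, ev.acceptor)
            per_frame_total[key] = per_frame_total.get(key, 0) + 1
            if (key, inst) in seen_this_frame:
                continue  # one bonded frame per instance even with two H routes
            seen_this_frame.add((key, inst))
            counts.setdefault(key, {})[inst] = counts.setdefault(key, {}).get(inst, 0) + 1
    if n_frames == 0:
        raise ValueError("trajectory holds no frames")

    keys = set(counts)
    if wanted is not None:
        selected = set()
        for label, cat in wanted:
            matches = [k for k in keys if k[0] == label and (cat is None or k[1] == cat)]
            if matches:
                selected.update(matches)
            else:
                selected.add((label, cat if cat is not None else "unobserved"))
        keys = selected

    rows = []
    for label, cat in sorted(keys):
        inst = counts.get((label, cat), {})
        occ = float(np.mean([c / n_frames for c in inst.values()])) if inst else 0.0
        rows.append(
            {
                "pair": label,
                "category": cat,
                "occupancy": occ,
                "mean_count": per_frame_total.get((label, cat), 0) / n_frames,
                "n_instances": len(inst),
                "n_frames": n_frames,
            }
        )
    return pd.DataFrame(rows, columns=["pair", "category", "occupancy", "mean_count", "n_instances", "n_frames"])


def per_instance_occupancy(
    trajectory: Trajectory,
    topology: FibrilTopology,
    label: str,
    criteria: HBondCriteria = HBondCriteria(),
    rules: Sequence[HBondRule] = DEFAULT_RULES,
) -> pd.DataFrame:
    """Diagnostic per-instance table for one pair label."""
    inst_counts: Dict[Tuple[int, int], int] = {}
    n_frames = 0
    for frame in trajectory.frames():
        events = detect_and_classify(frame, topology, criteria, frame_index=n_frames, rules=rules)
        n_frames += 1
        for ev in events:
            if ev.named_pair == label:
                inst_counts[(ev.donor, ev.acceptor)] = inst_counts.get((ev.donor, ev.acceptor), 0) + 1
    rows = [
        {"donor": d, "acceptor": a, "occupancy": c / n_frames}
        for (d, a), c in sorted(inst_counts.items())
    ]
    return pd.DataFrame(rows, columns=["donor", "acceptor", "occupancy"])


def inter_chain_count(
    frame: Structure,
    topology: FibrilTopology,
    criteria: HBondCriteria = HBondCriteria(),
) -> int:
    """Number of inter-chain (intra_sheet + inter_sheet) H-bond events."""
    events = detect_and_classify(frame, topology, criteria)
    return sum(1 for e in events if e.category in ("intra_sheet", "inter_sheet"))


def fraction_of_max(
    trajectory: Trajectory,
    reference: Structure,
    topology: FibrilTopology,
    criteria: HBondCriteria = HBondCriteria(),
) -> pd.DataFrame:
    """Per-frame inter-chain H-bond count relative to a reference structure.

    The series may exceed 1.  Raises if the reference has no inter-chain
    H-bonds under the same criteria.
    """
    ref_count = inter_chain_count(reference, topology, criteria)
    if ref_count == 0:
        raise ValueError("reference structure has zero inter-chain H-bonds")
    rows = []
    for i, frame in enumerate(trajectory.frames()):
        count = inter_chain_count(frame, topology, criteria)
        rows.append({"frame": i, "count": count, "fraction_of_max": count / ref_count})
    return pd.DataFrame(rows, columns=["frame", "count", "fraction_of_max"])
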