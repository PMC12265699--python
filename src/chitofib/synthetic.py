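"""Synthetic fibril trajectories with planted, fully known ground truth.

Every estimator in the package is validated by parameter recovery on
generator output.  Planting is geometric, never label-based: hydrogen bonds
are toggled by moving the donor hydrogen (and, where the lattice is too wide,
the acceptor) into or out of criterion geometry, waters are physically placed
at the planted sites, and sheet separations follow the planted schedule, so
detectors are exercised end-to-end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._template import DEFAULT_CELL_LENGTHS, TOY_CHARGES, WATER_ANGLE_DEG, WATER_OH
from .core import FibrilTopology, InMemoryTrajectory, Structure
from .crystal import CHITOSAN_CELL, FibrilSpec, build_fibril

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_trajectory",
    "generate_dewetting_scenario",
    "planted_dipole_chain",
]

_B = DEFAULT_CELL_LENGTHS[1]

#: Distance/angle geometry used when a bond is planted "on".
_ON_DISTANCE = 2.9
_H_BOND_LEN = 1.0
#: Template donor-acceptor distances above this require moving the acceptor.
_ACCEPTOR_MOVE_THRESHOLD = 3.3

_DONOR_H = {"O3": "HO3", "O6": "HO6", "N": "HN"}

Schedule = Union[float, int, Sequence[float], np.ndarray]


def _as_schedule(value: Schedule, n_frames: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        return np.full(n_frames, float(arr))
    if arr.shape != (n_frames,):
        raise ValueError(f"{name} schedule length {arr.shape} does not match n_frames={n_frames}")
    return arr


@dataclass
class SyntheticConfig:
    """Every planted parameter of a synthetic trajectory."""

    seed: int = 0
    n_frames: int = 100
    jitter_sigma: float = 0.05
    planted_occupancy: Dict[str, float] = field(default_factory=dict)
    stacking_schedule: Optional[Schedule] = None  # sheet separation Å; default b
    n_interior_waters: Schedule = 0
    n_bulk_waters: int = 0
    n_bridge_sites: int = 0
    bridge_survival_p: float = 1.0
    water_hbond_rates: Dict[str, float] = field(default_factory=dict)
    kappa: float = 0.0
    field_axis: str = "none"  # {"x", "y", "z", "none"}
    max_instances_per_pair: int = 30

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        for label, p in self.planted_occupancy.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"planted occupancy for {label!r} must lie in [0, 1]")
        if not (0.0 <= self.bridge_survival_p <= 1.0):
            raise ValueError("bridge_survival_p must lie in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.field_axis not in ("x", "y", "z", "none"):
            raise ValueError("field_axis must be one of x, y, z, none")

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "n_frames": self.n_frames,
            "jitter_sigma": self.jitter_sigma,
            "planted_occupancy": dict(self.planted_occupancy),
            "n_bulk_waters": self.n_bulk_waters,
            "n_bridge_sites": self.n_bridge_sites,
            "bridge_survival_p": self.bridge_survival_p,
            "water_hbond_rates": dict(self.water_hbond_rates),
            "kappa": self.kappa,
            "field_axis": self.field_axis,
            "max_instances_per_pair": self.max_instances_per_pair,
        }
        for key in ("stacking_schedule", "n_interior_waters"):
            v = getattr(self, key)
            if v is None or np.isscalar(v):
                d[key] = v
            else:
                d[key] = np.asarray(v).tolist()
        return d


@dataclass
class GroundTruth:
    """Planted values, recorded per frame, for generator-estimator round trips."""

    config: dict
    instance_counts: Dict[str, int]
    occupancy_states: Dict[str, np.ndarray]  # label -> per-frame on-counts
    stacking: np.ndarray
    interior_counts: np.ndarray  # scheduled free interior waters
    bridge_on: np.ndarray
    water_rate_events: Dict[str, np.ndarray]
    box: np.ndarray

    @property
    def interior_total(self) -> np.ndarray:
        """All planted waters in the interior slab (schedule + live bridges)."""
        return self.interior_counts + self.bridge_on

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "instance_counts": dict(self.instance_counts),
            "occupancy_states": {k: v.tolist() for k, v in self.occupancy_states.items()},
            "stacking": self.stacking.tolist(),
            "interior_counts": self.interior_counts.tolist(),
            "interior_total": self.interior_total.tolist(),
            "bridge_on": self.bridge_on.tolist(),
            "water_rate_events": {k: v.tolist() for k, v in self.water_rate_events.items()},
            "box": self.box.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# instance enumeration for planted hydrogen-bond labels


def _atom_index(structure: Structure, chain: str, res: int, name: str) -> Optional[int]:
    hits = np.flatnonzero(
        (structure.chain_id == chain)
        & (structure.res_index == res)
        & (structure.atom_name == name)
    )
    return int(hits[0]) if len(hits) else None


def _enumerate_instances(
    label: str,
    structure: Structure,
    topology: FibrilTopology,
    exclude_sheet_pairs: frozenset = frozenset(),
) -> List[Tuple[int, int, int]]:
    """All (donor, hydrogen, acceptor) triples matching a planted pair label.

    ``exclude_sheet_pairs`` drops inter-sheet instances spanning the given
    sheet pairs (used to keep planted bonds out of the interior gap when
    waters or bridges are planted there).
    """
    dp = topology.degree_of_polymerization
    out: List[Tuple[int, int, int]] = []

    def add(chain_d, res_d, dname, chain_a, res_a, aname):
        d = _atom_index(structure, chain_d, res_d, dname)
        a = _atom_index(structure, chain_a, res_a, aname)
        h = _atom_index(structure, chain_d, res_d, _DONOR_H[dname])
        if d is not None and a is not None and h is not None:
            out.append((d, h, a))

    if label == "O3′H–O5":
        for cid in topology.chains:
            for r in range(2, dp + 1):
                add(cid, r, "O3", cid, r - 1, "O5")
    elif label == "O6H–O3′":
        for cid in topology.chains:
            for r in range(1, dp):
                add(cid, r, "O6", cid, r + 1, "O3")
    elif label in ("N′H–O6", "O6H–N′"):
        for s in range(1, topology.n_sheets + 1):
            chains = topology.chains_in_sheet(s)
            for c1, c2 in zip(chains[:-1], chains[1:]):
                for r in range(1, dp + 1):
                    if label == "N′H–O6":
                        add(c2, r, "N", c1, r, "O6")
                    else:
                        add(c1, r, "O6", c2, r, "N")
    elif label == "N′H–O4":
        for s in range(1, topology.n_sheets):
            if frozenset((s, s + 1)) in exclude_sheet_pairs:
                continue
            lower = topology.chains_in_sheet(s)
            upper = topology.chains_in_sheet(s + 1)
            for c1, c2 in zip(lower, upper):
                for r in range(1, dp + 1):
                    add(c2, r, "N", c1, r, "O4")
    else:
        raise ValueError(f"unknown planted pair label {label!r}")
    return out


# ---------------------------------------------------------------------------
# water geometry helpers


def _perpendicular(d: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(d, trial)
    return e / np.linalg.norm(e)


def _water_coords(origin: np.ndarray, bisector: np.ndarray, azimuth: float) -> np.ndarray:
    """O, H1, H2 coordinates for a 3-site water with its dipole along ``bisector``."""
    d = bisector / np.linalg.norm(bisector)
    e1 = _perpendicular(d)
    e2 = np.cross(d, e1)
    e = np.cos(azimuth) * e1 + np.sin(azimuth) * e2
    half = np.deg2rad(WATER_ANGLE_DEG / 2.0)
    h1 = origin + WATER_OH * (np.cos(half) * d + np.sin(half) * e)
    h2 = origin + WATER_OH * (np.cos(half) * d - np.sin(half) * e)
    return np.vstack([origin, h1, h2])


def _sample_axis_angles(rng: np.random.Generator, n: int, kappa: float) -> np.ndarray:
    """Sample cos θ from p(c) ∝ exp(κ c) on [-1, 1] (κ = 0: isotropic)."""
    u = rng.random(n)
    if kappa < 1e-12:
        return 2.0 * u - 1.0
    # inverse CDF of the exponential tilt
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def _oriented_bisectors(rng: np.random.Generator, n: int, kappa: float, axis: np.ndarray) -> np.ndarray:
    cos_t = _sample_axis_angles(rng, n, kappa)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = rng.random(n) * 2.0 * np.pi
    e1 = _perpendicular(axis)
    e2 = np.cross(axis, e1)
    return (
        cos_t[:, None] * axis[None, :]
        + (sin_t * np.cos(phi))[:, None] * e1[None, :]
        + (sin_t * np.sin(phi))[:, None] * e2[None, :]
    )


_AXIS_VEC = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0]),
             "none": np.array([0, 0, 1.0])}


# ---------------------------------------------------------------------------
# system assembly


def _append_waters(parts: dict, chain: str, n: int, counters: dict) -> None:
    for _ in range(n):
        res = counters[chain] = counters.get(chain, 0) + 1
        parts["atom_name"].extend(["O", "H1", "H2"])
        parts["element"].extend(["O", "H", "H"])
        parts["res_name"].extend(["HOH"] * 3)
        parts["res_index"].extend([res] * 3)
        parts["chain_id"].extend([chain] * 3)


def _build_system(config: SyntheticConfig, base: Structure, topology: FibrilTopology):
    """Extend the fibril atom table with water slots; compute the box."""
    n_int_slots = int(np.max(_as_schedule(config.n_interior_waters, config.n_frames, "n_interior_waters")))
    rate_slots = {
        role: int(np.ceil(rate + 6.0 * np.sqrt(max(rate, 1.0)) + 5))
        for role, rate in config.water_hbond_rates.items()
    }

    parts = {k: [] for k in ("atom_name", "element", "res_name", "res_index", "chain_id")}
    slot_index = {}
    counters: dict = {}
    cursor = base.n_atoms
    for chain, count in (
        ("i", n_int_slots),
        ("b", config.n_bulk_waters),
        ("g", config.n_bridge_sites),
    ):
        _append_waters(parts, chain, count, counters)
        slot_index[chain] = [cursor + 3 * k for k in range(count)]
        cursor += 3 * count
    slot_index["rates"] = {}
    for role, count in rate_slots.items():
        _append_waters(parts, "r", count, counters)
        slot_index["rates"][role] = [cursor + 3 * k for k in range(count)]
        cursor += 3 * count

    n_new = len(parts["atom_name"])
    atom_name = np.concatenate([base.atom_name, np.array(parts["atom_name"], dtype="U6")]) if n_new else base.atom_name.copy()
    element = np.concatenate([base.element, np.array(parts["element"], dtype="U2")]) if n_new else base.element.copy()
    res_name = np.concatenate([base.res_name, np.array(parts["res_name"], dtype="U6")]) if n_new else base.res_name.copy()
    res_index = np.concatenate([base.res_index, np.array(parts["res_index"], dtype=np.int64)]) if n_new else base.res_index.copy()
    chain_id = np.concatenate([base.chain_id, np.array(parts["chain_id"], dtype="U4")]) if n_new else base.chain_id.copy()
    coords = np.vstack([base.coords, np.zeros((n_new, 3))]) if n_new else base.coords.copy()

    charges = np.array(
        [TOY_CHARGES.get((rn, an), 0.0) for rn, an in zip(res_name, atom_name)]
    )

    fib_min = base.coords.min(axis=0)
    fib_max = base.coords.max(axis=0)
    box = np.array(
        [
            fib_max[0] - min(fib_min[0], 0.0) + 40.0,
            fib_max[1] + 20.0,
            fib_max[2] + 20.0,
        ]
    )
    bulk_region = (fib_max[0] + 11.0, fib_max[0] + 29.0)

    system = Structure(
        atom_name=atom_name,
        element=element,
        res_name=res_name,
        res_index=res_index,
        chain_id=chain_id,
        coords=coords,
        charges=charges,
        box=box,
    )
    return system, slot_index, bulk_region


def generate_trajectory(
    config: SyntheticConfig,
    base: Optional[Structure] = None,
    topology: Optional[FibrilTopology] = None,
    spec: Optional[FibrilSpec] = None,
) -> Tuple[InMemoryTrajectory, GroundTruth]:
    """Generate a trajectory with planted ground truth.

    Deterministic given ``config.seed``.  Returns the trajectory (whose atom
    table carries toy charges) and the :class:`GroundTruth` record.
    """
    if base is None or topology is None:
        base, topology = build_fibril(CHITOSAN_CELL, spec=spec)
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames

    stacking = _as_schedule(
        config.stacking_schedule if config.stacking_schedule is not None else _B,
        n_frames,
        "stacking",
    )
    interior_schedule = _as_schedule(config.n_interior_waters, n_frames, "n_interior_waters").astype(int)
    if interior_schedule.max() > 0 and topology.n_sheets < 4:
        raise ValueError("interior waters require a fibril with >= 4 sheets")

    system, slots, bulk_region = _build_system(config, base, topology)
    n_fibril = base.n_atoms
    field_axis = _AXIS_VEC[config.field_axis]

    # --- planted H-bond instance registry (no shared donor hydrogens) ---
    # Keep planted inter-sheet bonds out of the interior gap when waters or
    # bridges are planted there, so the plantings stay independent.
    exclude_pairs = frozenset()
    if topology.n_sheets >= 4 and (config.n_bridge_sites > 0 or interior_schedule.max() > 0):
        exclude_pairs = frozenset({frozenset(topology.interior_sheets())})
    registry: Dict[str, List[Tuple[int, int, int]]] = {}
    used_h = set()
    for label, p in config.planted_occupancy.items():
        candidates = _enumerate_instances(label, base, topology, exclude_pairs)
        rng.shuffle(candidates)
        chosen = []
        for inst in candidates:
            if inst[1] in used_h:
                continue
            chosen.append(inst)
            used_h.add(inst[1])
            if len(chosen) >= config.max_instances_per_pair:
                break
        if not chosen:
            raise ValueError(f"no plantable instances for label {label!r}")
        registry[label] = chosen

    # unit vectors and base distances per instance (from the base fibril)
    inst_geometry = {}
    for label, instances in registry.items():
        geo = []
        for d, h, a in instances:
            u = base.coords[a] - base.coords[d]
            dist = np.linalg.norm(u)
            geo.append((u / dist, dist))
        inst_geometry[label] = geo

    # --- bridge sites between the two interior sheets ---
    bridge_sites = []
    if config.n_bridge_sites:
        s2, s3 = topology.interior_sheets()
        lo_chains = topology.chains_in_sheet(s2)
        hi_chains = topology.chains_in_sheet(s3)
        dp = topology.degree_of_polymerization
        res_positions = np.linspace(2, dp - 1, config.n_bridge_sites).astype(int)
        for m in range(config.n_bridge_sites):
            c_lo = lo_chains[m % len(lo_chains)]
            c_hi = hi_chains[m % len(hi_chains)]
            r = int(res_positions[m])
            a1 = _atom_index(base, c_lo, r, "O6")
            h1 = _atom_index(base, c_lo, r, "HO6")
            # partner N on the (antiparallel) upper chain, matched by z proximity
            n_pool = np.flatnonzero(
                (base.chain_id == c_hi) & (base.atom_name == "N")
            )
            a2 = int(n_pool[np.argmin(np.abs(base.coords[n_pool, 2] - base.coords[a1, 2]))])
            h2 = _atom_index(base, c_hi, int(base.res_index[a2]), "HN")
            bridge_sites.append((a1, h1, a2, h2))
    bridge_anchor_xz = np.array(
        [
            0.5 * (base.coords[a1, [0, 2]] + base.coords[a2, [0, 2]])
            for a1, _, a2, _ in bridge_sites
        ]
    ).reshape(-1, 2)

    # --- per-frame sheet shifts ---
    sheet_masks = {
        s: np.isin(system.chain_id, topology.chains_in_sheet(s))
        for s in range(1, topology.n_sheets + 1)
    }
    base_sheet_y = {s: (s - 1) * _B for s in range(1, topology.n_sheets + 1)}
    y_center = float(np.mean(list(base_sheet_y.values())))
    mid = (topology.n_sheets - 1) / 2.0

    # interior placement bounds from the base interior sheets
    s2, s3 = topology.interior_sheets() if topology.n_sheets >= 4 else (1, topology.n_sheets)
    int_mask = np.isin(base.chain_id, topology.chains_in_sheet(s2) + topology.chains_in_sheet(s3))
    int_heavy = int_mask & base.heavy
    xlo, xhi = base.coords[int_heavy, 0].min() + 0.5, base.coords[int_heavy, 0].max() - 0.5
    zlo, zhi = base.coords[int_heavy, 2].min() + 0.5, base.coords[int_heavy, 2].max() - 0.5

    coords_out = np.empty((n_frames, system.n_atoms, 3))
    occupancy_states = {label: np.zeros(n_frames, dtype=int) for label in registry}
    bridge_on = np.zeros(n_frames, dtype=int)
    rate_events = {role: np.zeros(n_frames, dtype=int) for role in config.water_hbond_rates}

    park_x = np.linspace(bulk_region[0], bulk_region[1], 8)

    interior_roles = {"O6H": "O6", "O3H": "O3", "NH": "N"}
    interior_chain_set = (
        topology.interior_chains() if topology.n_sheets >= 4 else topology.chains
    )
    role_site_pool: Dict[str, np.ndarray] = {}
    for role in config.water_hbond_rates:
        heavy_name = interior_roles.get(role, role)
        pool = np.flatnonzero(
            np.isin(base.chain_id, interior_chain_set) & (base.atom_name == heavy_name)
        )
        if len(pool) == 0:
            raise ValueError(f"no interior-site atoms for water H-bond role {role!r}")
        role_site_pool[role] = pool

    for t in range(n_frames):
        frame = np.array(system.coords)
        frame[:n_fibril] = base.coords

        # sheet stacking shifts (fibril atoms only at this point)
        sep = stacking[t]
        sheet_plane = {}
        for s in range(1, topology.n_sheets + 1):
            target = y_center + (s - 1 - mid) * sep
            frame[sheet_masks[s], 1] += target - base_sheet_y[s]
            sheet_plane[s] = target

        # thermal disorder on chitosan atoms
        if config.jitter_sigma > 0:
            frame[:n_fibril] += rng.normal(0.0, config.jitter_sigma, (n_fibril, 3))

        # planted H-bond toggles
        for label, instances in registry.items():
            p = config.planted_occupancy[label]
            states = rng.random(len(instances)) < p
            occupancy_states[label][t] = int(states.sum())
            for (didx, hidx, aidx), (u, dist0), on in zip(
                instances, inst_geometry[label], states
            ):
                dpos = frame[didx]
                if on:
                    frame[hidx] = dpos + _H_BOND_LEN * u
                    if dist0 > _ACCEPTOR_MOVE_THRESHOLD:
                        frame[aidx] = dpos + _ON_DISTANCE * u
                else:
                    frame[hidx] = dpos - _H_BOND_LEN * u

        # interior waters
        n_int = interior_schedule[t]
        islots = slots["i"]
        y_lo = sheet_plane[s2] + 2.2
        y_hi = sheet_plane[s3] - 2.2
        for k, start in enumerate(islots):
            if k < n_int:
                # keep free interior waters clear of the planted bridge sites
                for _ in range(200):
                    origin = np.array(
                        [
                            rng.uniform(xlo, xhi),
                            rng.uniform(y_lo, y_hi),
                            rng.uniform(zlo, zhi),
                        ]
                    )
                    if len(bridge_anchor_xz) == 0 or np.all(
                        np.linalg.norm(bridge_anchor_xz - origin[[0, 2]], axis=1) > 4.5
                    ):
                        break
                bis = _oriented_bisectors(rng, 1, 0.0, field_axis)[0]
            else:
                origin = np.array(
                    [park_x[k % len(park_x)], 6.0 + 2.5 * (k // len(park_x)), 6.0 + 0.9 * k]
                )
                bis = _oriented_bisectors(rng, 1, 0.0, field_axis)[0]
            frame[start : start + 3] = _water_coords(origin, bis, rng.random() * 2 * np.pi)

        # bulk waters with κ-concentrated dipole orientations
        bslots = slots["b"]
        if bslots:
            n_b = len(bslots)
            origins = np.column_stack(
                [
                    rng.uniform(bulk_region[0], bulk_region[1], n_b),
                    rng.uniform(5.0, system.box[1] - 5.0, n_b),
                    rng.uniform(5.0, system.box[2] - 5.0, n_b),
                ]
            )
            bis = _oriented_bisectors(rng, n_b, config.kappa, field_axis)
            az = rng.random(n_b) * 2 * np.pi
            for k, start in enumerate(bslots):
                frame[start : start + 3] = _water_coords(origins[k], bis[k], az[k])

        # planted water bridges between the interior sheets
        gslots = slots["g"]
        phi = np.deg2rad(WATER_ANGLE_DEG / 2.0)
        d1 = np.array([np.sin(phi), -np.cos(phi), 0.0])
        d2 = np.array([np.sin(phi), np.cos(phi), 0.0])
        for k, ((a1, h1, a2, h2), start) in enumerate(zip(bridge_sites, gslots)):
            on = rng.random() < config.bridge_survival_p
            if on:
                bridge_on[t] += 1
                anchor_x = 0.5 * (frame[a1, 0] + frame[a2, 0])
                anchor_z = 0.5 * (frame[a1, 2] + frame[a2, 2])
                p = np.array([anchor_x, 0.5 * (sheet_plane[s2] + sheet_plane[s3]), anchor_z])
                frame[a1] = p + 2.8 * d1
                frame[a2] = p + 2.8 * d2
                # re-attach the partners' own hydrogens pointing away from the water
                frame[h1] = frame[a1] + 0.97 * d1
                frame[h2] = frame[a2] + 0.97 * d2
                frame[start] = p
                frame[start + 1] = p + WATER_OH * d1
                frame[start + 2] = p + WATER_OH * d2
            else:
                origin = np.array([park_x[k % len(park_x)], system.box[1] - 8.0, 8.0 + 3.1 * k])
                bis = _oriented_bisectors(rng, 1, 0.0, field_axis)[0]
                frame[start : start + 3] = _water_coords(origin, bis, rng.random() * 2 * np.pi)

        # planted chitosan-water H-bond events by atom role
        used_sites = set()
        for role, rate in config.water_hbond_rates.items():
            rslots = slots["rates"][role]
            k_events = min(int(rng.poisson(rate)), len(rslots))
            rate_events[role][t] = k_events
            pool = [i for i in role_site_pool[role] if i not in used_sites]
            rng.shuffle(pool)
            chosen_sites = pool[:k_events]
            used_sites.update(chosen_sites)
            for k, start in enumerate(rslots):
                if k < len(chosen_sites):
                    site = chosen_sites[k]
                    sheet = topology.chain_to_sheet[base.chain_id[site]]
                    d = np.array([0.0, 1.0, 0.0]) if sheet == s2 else np.array([0.0, -1.0, 0.0])
                    apos = frame[site]
                    if role in interior_roles:  # chitosan donates to the water
                        hname = _DONOR_H[interior_roles[role]]
                        hidx = _atom_index(
                            base, base.chain_id[site], int(base.res_index[site]), hname
                        )
                        frame[hidx] = apos + 0.97 * d
                        frame[start : start + 3] = _water_coords(apos + 2.85 * d, d, 0.0)
                    else:  # water donates to the chitosan acceptor
                        if role in _DONOR_H:  # point any attached H away first
                            hidx = _atom_index(
                                base, base.chain_id[site], int(base.res_index[site]), _DONOR_H[role]
                            )
                            if hidx is not None:
                                frame[hidx] = apos - 0.97 * d
                        o_w = apos + 2.85 * d
                        h1 = o_w - WATER_OH * d
                        e = _perpendicular(d)
                        d2v = np.cos(np.deg2rad(WATER_ANGLE_DEG)) * (-d) + np.sin(
                            np.deg2rad(WATER_ANGLE_DEG)
                        ) * e
                        h2v = o_w + WATER_OH * d2v
                        frame[start : start + 3] = np.vstack([o_w, h1, h2v])
                else:
                    origin = np.array(
                        [park_x[(k + 3) % len(park_x)], system.box[1] - 14.0, 8.0 + 2.7 * (start % 29)]
                    )
                    bis = _oriented_bisectors(rng, 1, 0.0, field_axis)[0]
                    frame[start : start + 3] = _water_coords(origin, bis, rng.random() * 2 * np.pi)

        coords_out[t] = frame

    boxes = np.tile(system.box, (n_frames, 1))
    trajectory = InMemoryTrajectory(system, coords_out, boxes)
    truth = GroundTruth(
        config=config.to_dict(),
        instance_counts={label: len(v) for label, v in registry.items()},
        occupancy_states=occupancy_states,
        stacking=stacking,
        interior_counts=interior_schedule,
        bridge_on=bridge_on,
        water_rate_events=rate_events,
        box=system.box,
    )
    return trajectory, truth


def generate_dewetting_scenario(
    seed: int = 0,
    n_frames: int = 120,
    contraction: float = 0.6,
    spec: Optional[FibrilSpec] = None,
    field_off: Optional[SyntheticConfig] = None,
    field_on: Optional[SyntheticConfig] = None,
) -> Dict[str, Tuple[InMemoryTrajectory, GroundTruth]]:
    """Paired field-off / field-on trajectories emulating a dewetting contrast.

    Field-off: flat stacking at the lattice spacing, broad interior-water
    schedule, isotropic bulk-water dipoles, high bridge survival.  Field-on:
    stacking reduced by ``contraction`` Å, interior water decaying, raised
    planted inter-sheet occupancy, aligned bulk dipoles, low bridge survival.
    """
    base, topology = build_fibril(CHITOSAN_CELL, spec=spec)
    rng = np.random.default_rng(seed)
    broad = rng.integers(18, 43, size=n_frames)
    decay = np.round(np.linspace(30, 5, n_frames)).astype(int)

    off = field_off or SyntheticConfig(
        seed=seed,
        n_frames=n_frames,
        jitter_sigma=0.06,
        planted_occupancy={"N′H–O4": 0.55},
        stacking_schedule=_B,
        n_interior_waters=broad,
        n_bulk_waters=40,
        n_bridge_sites=6,
        bridge_survival_p=0.7,
        kappa=0.0,
        field_axis="none",
    )
    on = field_on or SyntheticConfig(
        seed=seed + 1,
        n_frames=n_frames,
        jitter_sigma=0.06,
        planted_occupancy={"N′H–O4": 0.75},
        stacking_schedule=_B - contraction,
        n_interior_waters=decay,
        n_bulk_waters=40,
        n_bridge_sites=6,
        bridge_survival_p=0.25,
        kappa=2.0,
        field_axis="z",
    )
    return {
        "field_off": generate_trajectory(off, base=base, topology=topology),
        "field_on": generate_trajectory(on, base=base, topology=topology),
    }


def planted_dipole_chain(
    theta_deg: float, n_residues: int = 20, rise: float = 5.0, azimuth_deg: float = 0.0
):
    """A straight synthetic chain whose dipole makes a known angle with its axis.

    Each residue is a ±0.5 e charge pair whose separation vector points at
    ``theta_deg`` from the chain (z) axis.  Returns (structure, charge dict)
    where the charge dict plugs into :class:`chitofib.dipoles.ChargeTable`.
    """
    theta = np.deg2rad(theta_deg)
    az = np.deg2rad(azimuth_deg)
    d = np.array(
        [np.sin(theta) * np.cos(az), np.sin(theta) * np.sin(az), np.cos(theta)]
    )
    names, elements, res_names, res_idx, chain_ids, coords = [], [], [], [], [], []
    for r in range(1, n_residues + 1):
        center = np.array([0.0, 0.0, r * rise])
        for name, sign in (("QP", 1.0), ("QM", -1.0)):
            names.append(name)
            elements.append("C")
            res_names.append("DIP")
            res_idx.append(r)
            chain_ids.append("A")
            coords.append(center + 0.5 * sign * d)
    structure = Structure(
        atom_name=np.array(names),
        element=np.array(elements),
        res_name=np.array(res_names),
        res_index=np.array(res_idx, dtype=np.int64),
        chain_id=np.array(chain_ids),
        coords=np.array(coords),
    )
    return structure, {("DIP", "QP"): 0.5, ("DIP", "QM"): -0.5}
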