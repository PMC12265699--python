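import math

import numpy as np
import pytest
from scipy.stats import binom

from chitofib.core import FibrilTopology, InMemoryTrajectory
from chitofib.hbonds import (
    HBondCriteria,
    HBondEvent,
    classify_hbond,
    detect_and_classify,
    detect_hbonds,
    fraction_of_max,
    inter_chain_count,
    occupancy,
)
from chitofib.crystal import CHITOSAN_CELL, FibrilSpec, build_fibril
from chitofib.synthetic import SyntheticConfig, generate_trajectory

from conftest import make_structure, single_chain_topology

# ---------------------------------------------------------------------------
# independent brute-force oracle (no trees, no package helpers)

_SUGAR_H = {"HO3": "O3", "HO6": "O6", "HN": "N", "HN2": "N"}
_WATER_H = {"H1": "O", "H2": "O"}
_SUGAR_ACC = {"N", "O3", "O4", "O5", "O6"}
_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}


def brute_force_hbonds(frame, criteria):
    """Exhaustive O(N^2 * H) enumeration of donor-H-acceptor triples."""

    def mimg(v):
        if frame.box is None:
            return v
        return v - frame.box * np.round(v / frame.box)

    n = frame.n_atoms
    res_of = [(frame.chain_id[i], int(frame.res_index[i])) for i in range(n)]
    is_w = [frame.res_name[i] in _WATER_NAMES for i in range(n)]

    donors = {}
    for i in range(n):
        hmap = _WATER_H if is_w[i] else _SUGAR_H
        if frame.atom_name[i] in hmap:
            parent = [
                j
                for j in range(n)
                if res_of[j] == res_of[i] and frame.atom_name[j] == hmap[frame.atom_name[i]]
            ][0]
            donors.setdefault(parent, []).append(i)

    acceptors = [
        i
        for i in range(n)
        if (is_w[i] and frame.element[i] == "O")
        or (not is_w[i] and frame.atom_name[i] in _SUGAR_ACC)
    ]

    triples = set()
    for d, hs in donors.items():
        for a in acceptors:
            if a == d or res_of[a] == res_of[d]:
                continue
            if np.linalg.norm(mimg(frame.coords[a] - frame.coords[d])) >= criteria.max_distance:
                continue
            for h in hs:
                v1 = mimg(frame.coords[d] - frame.coords[h])
                v2 = mimg(frame.coords[a] - frame.coords[h])
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle > criteria.min_angle:
                    triples.add((d, h, a))
    return triples


def random_frame(rng, n_hydroxyls=30, n_waters=20, box=None, spread=12.0):
    atoms = []
    res = 1
    for _ in range(n_hydroxyls):
        o = rng.uniform(0, spread, 3)
        h = o + rng.normal(size=3) * 0.4 + 0.5
        atoms.append(("O3", "O", "GCS", res, "A", o))
        atoms.append(("HO3", "H", "GCS", res, "A", h))
        atoms.append(("O5", "O", "GCS", res, "A", rng.uniform(0, spread, 3)))
        res += 1
    for _ in range(n_waters):
        o = rng.uniform(0, spread, 3)
        d1 = rng.normal(size=3)
        d1 /= np.linalg.norm(d1)
        d2 = rng.normal(size=3)
        d2 /= np.linalg.norm(d2)
        atoms.append(("O", "O", "HOH", res, "W", o))
        atoms.append(("H1", "H", "HOH", res, "W", o + 0.96 * d1))
        atoms.append(("H2", "H", "HOH", res, "W", o + 0.96 * d2))
        res += 1
    return make_structure(atoms, box=box)


# ---------------------------------------------------------------------------


def test_criteria_validation():
    with pytest.raises(ValueError):
        HBondCriteria(max_distance=-1.0)
    with pytest.raises(ValueError):
        HBondCriteria(min_angle=0.0)
    with pytest.raises(ValueError):
        HBondCriteria(min_angle=181.0)


def test_distance_just_over_threshold_rejected():
    frame = make_structure(
        [
            ("O3", "O", "GCS", 1, "A", (0.0, 0.0, 0.0)),
            ("HO3", "H", "GCS", 1, "A", (1.0, 0.0, 0.0)),
            ("O5", "O", "GCS", 2, "A", (3.6, 0.0, 0.0)),
        ]
    )
    assert detect_hbonds(frame) == []


def test_ideal_collinear_geometry_accepted():
    frame = make_structure(
        [
            ("O3", "O", "GCS", 1, "A", (0.0, 0.0, 0.0)),
            ("HO3", "H", "GCS", 1, "A", (1.0, 0.0, 0.0)),
            ("O5", "O", "GCS", 2, "A", (2.8, 0.0, 0.0)),
        ]
    )
    events = detect_hbonds(frame)
    assert [e.triple() for e in events] == [(0, 1, 2)]


def test_donor_without_hydrogen_rejected():
    frame = make_structure(
        [
            ("O", "O", "HOH", 1, "W", (0.0, 0.0, 0.0)),
            ("H1", "H", "HOH", 1, "W", (0.96, 0.0, 0.0)),
        ]
    )
    with pytest.raises(ValueError, match="two hydrogens"):
        detect_hbonds(frame)


def test_toy_frame_matches_bruteforce(rng):
    # two hydroxyls + one water, hand-placed
    frame = make_structure(
        [
            ("O3", "O", "GCS", 1, "A", (0.0, 0.0, 0.0)),
            ("HO3", "H", "GCS", 1, "A", (0.97, 0.0, 0.0)),
            ("O6", "O", "GCS", 2, "A", (2.9, 0.0, 0.0)),
            ("HO6", "H", "GCS", 2, "A", (2.9, 0.97, 0.0)),
            ("O", "O", "HOH", 3, "W", (2.9, 3.0, 0.0)),
            ("H1", "H", "HOH", 3, "W", (2.9, 2.2, 0.0)),
            ("H2", "H", "HOH", 3, "W", (3.6, 3.5, 0.0)),
        ]
    )
    got = {e.triple() for e in detect_hbonds(frame)}
    assert got == brute_force_hbonds(frame, HBondCriteria())
    assert len(got) >= 2  # O3H->O6 and water H1 route or O6H->water


@pytest.mark.parametrize("seed", range(6))
def test_random_frames_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    box = np.array([14.0, 14.0, 14.0]) if seed % 2 else None
    frame = random_frame(rng, n_hydroxyls=25, n_waters=20, box=box)
    assert frame.n_atoms <= 200
    got = {e.triple() for e in detect_hbonds(frame)}
    expected = brute_force_hbonds(frame, HBondCriteria())
    assert got == expected


@pytest.mark.parametrize("seed", [11, 12])
def test_monotonicity_under_relaxed_criteria(seed):
    rng = np.random.default_rng(seed)
    frame = random_frame(rng, n_hydroxyls=20, n_waters=15)
    strict = {e.triple() for e in detect_hbonds(frame, HBondCriteria(3.2, 150.0))}
    relaxed = {e.triple() for e in detect_hbonds(frame, HBondCriteria(3.8, 120.0))}
    assert strict <= relaxed


def test_minimum_image_detection_across_boundary():
    box = np.array([10.0, 10.0, 10.0])
    frame = make_structure(
        [
            ("O3", "O", "GCS", 1, "A", (0.5, 5.0, 5.0)),
            ("HO3", "H", "GCS", 1, "A", (-0.5, 5.0, 5.0)),  # points across x boundary
            ("O5", "O", "GCS", 2, "A", (8.0, 5.0, 5.0)),  # 2.5 Å away via wrap
        ],
        box=box,
    )
    events = detect_hbonds(frame)
    assert [e.triple() for e in events] == [(0, 1, 2)]
    # without the box the pair is 7.5 Å apart and no bond is found
    unboxed = make_structure(
        [
            ("O3", "O", "GCS", 1, "A", (0.5, 5.0, 5.0)),
            ("HO3", "H", "GCS", 1, "A", (-0.5, 5.0, 5.0)),
            ("O5", "O", "GCS", 2, "A", (8.0, 5.0, 5.0)),
        ]
    )
    assert detect_hbonds(unboxed) == []


class TestClassification:
    def test_intra_sheet_o6_to_n(self, small_fibril):
        structure, topology, _ = small_fibril
        events = detect_and_classify(structure, topology)
        intra_sheet = [e for e in events if e.category == "intra_sheet"]
        assert intra_sheet and all(e.named_pair == "O6H–N′" for e in intra_sheet)
        ev = intra_sheet[0]
        assert structure.chain_id[ev.donor] != structure.chain_id[ev.acceptor]
        assert (
            topology.chain_to_sheet[structure.chain_id[ev.donor]]
            == topology.chain_to_sheet[structure.chain_id[ev.acceptor]]
        )

    def test_inter_sheet_nh_o4(self, small_fibril):
        structure, topology, _ = small_fibril
        # construct the event explicitly: donor N on sheet 1, acceptor O4 on sheet 2
        dchain = topology.chains_in_sheet(1)[0]
        achain = topology.chains_in_sheet(2)[0]
        d = np.flatnonzero((structure.chain_id == dchain) & (structure.atom_name == "N"))[0]
        h = np.flatnonzero((structure.chain_id == dchain) & (structure.atom_name == "HN"))[0]
        a = np.flatnonzero((structure.chain_id == achain) & (structure.atom_name == "O4"))[0]
        ev = classify_hbond(HBondEvent(0, int(d), int(h), int(a)), structure, topology)
        assert ev.category == "inter_sheet"
        assert ev.named_pair == "N′H–O4"

    def test_intra_chain_o3_o5_offset(self, small_fibril):
        structure, topology, _ = small_fibril
        events = detect_and_classify(structure, topology)
        intra = [e for e in events if e.category == "intra_chain"]
        assert intra and all(e.named_pair == "O3′H–O5" for e in intra)
        for ev in intra[:5]:
            assert structure.res_index[ev.donor] - structure.res_index[ev.acceptor] == 1

    def test_partition_property(self, small_fibril):
        structure, topology, _ = small_fibril
        events = detect_and_classify(structure, topology)
        cats = {e.category for e in events}
        assert cats <= {"intra_chain", "intra_sheet", "inter_sheet"}
        counts = sum(
            sum(1 for e in events if e.category == c)
            for c in ("intra_chain", "intra_sheet", "inter_sheet")
        )
        assert counts == len(events)

    def test_unknown_atom_rejected(self, small_fibril):
        structure, topology, _ = small_fibril
        bad = structure.copy()
        bad.chain_id = bad.chain_id.copy()
        bad.chain_id[0] = "ZZ"
        ev = HBondEvent(0, 0, 1, 2)
        with pytest.raises(ValueError, match="neither water nor in the topology"):
            classify_hbond(ev, bad, topology)


def _four_frame_trajectory():
    """One O3'H-O5 instance bonded in 3 of 4 frames."""
    base = make_structure(
        [
            ("O5", "O", "GCS", 1, "A", (0.0, 0.0, 0.0)),
            ("O3", "O", "GCS", 2, "A", (2.8, 0.0, 0.0)),
            ("HO3", "H", "GCS", 2, "A", (1.83, 0.0, 0.0)),
        ]
    )
    on = base.coords.copy()
    off = base.coords.copy()
    off[2] = [3.77, 0.0, 0.0]  # hydrogen flipped away
    coords = np.array([on, on, off, on])
    return InMemoryTrajectory(base, coords), single_chain_topology(2)


def test_occupancy_three_of_four_frames():
    traj, topo = _four_frame_trajectory()
    table = occupancy(traj, topo, pairs=["O3′H–O5"])
    assert table.occupancy.tolist() == [0.75]
    assert table.n_frames.tolist() == [4]


def test_occupancy_never_formed_is_zero():
    traj, topo = _four_frame_trajectory()
    table = occupancy(traj, topo, pairs=["N′H–O4"])
    assert table.occupancy.tolist() == [0.0]


def test_occupancy_empty_trajectory_rejected():
    traj, topo = _four_frame_trajectory()
    empty = InMemoryTrajectory(traj.atoms, traj.coords[:0])
    with pytest.raises(ValueError):
        occupancy(empty, topo)


def test_occupancy_recovers_planted_probability(small_fibril):
    # [DERIVED] binomial-interval oracle: planted p = 0.8 over 500 frames
    structure, topology, _ = small_fibril
    p, n_frames = 0.8, 500
    cfg = SyntheticConfig(
        seed=42, n_frames=n_frames, jitter_sigma=0.03, planted_occupancy={"N′H–O4": p}
    )
    traj, truth = generate_trajectory(cfg, base=structure, topology=topology)
    table = occupancy(traj, topology, pairs=["N′H–O4"])
    est = table.occupancy[0]
    n_draws = truth.instance_counts["N′H–O4"] * n_frames
    lo = binom.ppf(0.005, n_draws, p) / n_draws
    hi = binom.ppf(0.995, n_draws, p) / n_draws
    assert lo <= est <= hi


def _two_sheet_single_chain():
    spec = FibrilSpec(n_sheets=2, chains_per_sheet=1, degree_of_polymerization=20)
    return build_fibril(CHITOSAN_CELL, spec=spec), spec


class TestFractionOfMax:
    def test_self_reference_is_one(self, small_fibril):
        structure, topology, _ = small_fibril
        traj = InMemoryTrajectory(structure, structure.coords[None])
        frac = fraction_of_max(traj, structure, topology)
        assert frac.fraction_of_max.tolist() == [1.0]

    def test_all_broken_is_zero(self, small_fibril):
        structure, topology, _ = small_fibril
        broken = structure.copy()
        ho6 = structure.atom_name == "HO6"
        o6 = structure.atom_name == "O6"
        # flip every O6 hydroxyl hydrogen through its oxygen
        broken.coords[ho6] = 2 * structure.coords[o6] - structure.coords[ho6]
        traj = InMemoryTrajectory(broken, broken.coords[None])
        frac = fraction_of_max(traj, structure, topology)
        assert frac.fraction_of_max.tolist() == [0.0]

    def test_zero_reference_rejected(self):
        (structure, topology), _ = _two_sheet_single_chain()
        traj = InMemoryTrajectory(structure, structure.coords[None])
        with pytest.raises(ValueError, match="zero inter-chain"):
            fraction_of_max(traj, structure, topology)

    def test_planted_sixty_percent(self):
        # [DERIVED] a 2-sheet single-chain fibril has no natural inter-chain
        # bonds; reference = all planted instances on, trajectory plants 60 %
        (structure, topology), _ = _two_sheet_single_chain()
        ref_cfg = SyntheticConfig(seed=7, n_frames=1, jitter_sigma=0.0,
                                  planted_occupancy={"N′H–O4": 1.0})
        ref_traj, _ = generate_trajectory(ref_cfg, base=structure, topology=topology)
        reference = ref_traj.frame(0)
        assert inter_chain_count(reference, topology) == 20

        cfg = SyntheticConfig(seed=8, n_frames=120, jitter_sigma=0.03,
                              planted_occupancy={"N′H–O4": 0.6})
        traj, truth = generate_trajectory(cfg, base=structure, topology=topology)
        frac = fraction_of_max(traj, reference, topology)
        planted_mean = truth.occupancy_states["N′H–O4"].mean() / 20
        assert frac.fraction_of_max.mean() == pytest.approx(planted_mean, abs=1e-9)
        assert frac.fraction_of_max.mean() == pytest.approx(0.6, abs=0.04)


def test_occupancy_invariant_under_chain_relabeling(small_fibril):
    structure, topology, _ = small_fibril
    traj = InMemoryTrajectory(structure, structure.coords[None])
    t1 = occupancy(traj, topology, pairs=["O6H–N′"])
    # relabel chains by swapping the two chains of each sheet
    mapping = {}
    for s in range(1, topology.n_sheets + 1):
        a, b = topology.chains_in_sheet(s)
        mapping[a], mapping[b] = b, a
    relabeled = structure.copy()
    relabeled.chain_id = np.array([mapping[c] for c in structure.chain_id])
    traj2 = InMemoryTrajectory(relabeled, relabeled.coords[None])
    t2 = occupancy(traj2, topology, pairs=["O6H–N′"])
    assert t1.occupancy.tolist() == t2.occupancy.tolist()
    assert t1.mean_count.tolist() == t2.mean_count.tolist()
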