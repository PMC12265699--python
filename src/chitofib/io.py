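"""Readers and writers: PDB/mmCIF structures, multi-model PDB and DCD
trajectories, charge tables and run manifests.

PDB and mmCIF parsing is delegated to biotite; DCD I/O to MDAnalysis.  DCD
trajectories are streamed frame by frame (constant memory per frame).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

from .core import FibrilTopology, InMemoryTrajectory, Structure, Trajectory

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory_pdb",
    "write_trajectory_dcd",
    "topology_sidecar_path",
    "write_manifest",
    "config_hash",
]


def topology_sidecar_path(structure_path) -> Path:
    p = Path(structure_path)
    return p.with_suffix(".topology.json")


def _from_atom_array(arr, box_mat) -> Structure:
    box = None
    if box_mat is not None:
        diag = np.diagonal(np.asarray(box_mat))
        if np.any(diag > 0):
            off = np.asarray(box_mat) - np.diag(diag)
            if not np.allclose(off, 0.0, atol=1e-6):
                raise ValueError("only orthorhombic boxes are supported")
            box = diag.copy()
    element = np.asarray(arr.element, dtype="U2")
    element = np.char.upper(element)
    return Structure(
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        element=element,
        res_name=np.asarray(arr.res_name, dtype="U6"),
        res_index=np.asarray(arr.res_id, dtype=np.int64),
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
        coords=np.asarray(arr.coord, dtype=np.float64),
        box=box,
    )


def _to_atom_array(structure: Structure):
    import biotite.structure as struc

    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.chain_id = structure.chain_id
    arr.res_id = structure.res_index
    arr.res_name = structure.res_name
    arr.atom_name = structure.atom_name
    arr.element = structure.element
    arr.hetero = structure.is_water
    if structure.box is not None:
        arr.box = np.diag(structure.box)
    return arr


def read_structure(path, fmt: Optional[str] = None) -> Structure:
    """Read a Structure from PDB or mmCIF.

    The format is inferred from the extension unless given.  A topology
    sidecar (``<stem>.topology.json``) is loaded automatically when present;
    otherwise the structure is returned without one and topology-driven
    classification is unavailable.

    Returns the structure; use :func:`read_structure_with_topology` to also
    get the sidecar.
    """
    structure, _ = read_structure_with_topology(path, fmt)
    return structure


def read_structure_with_topology(path, fmt: Optional[str] = None):
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty structure file")
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    try:
        if fmt == "pdb":
            import biotite.structure.io.pdb as pdbio

            f = pdbio.PDBFile.read(str(path))
            arr = f.get_structure(model=1)
            box = arr.box
        elif fmt in ("cif", "mmcif", "pdbx"):
            import biotite.structure.io.pdbx as pdbx

            f = pdbx.CIFFile.read(str(path))
            arr = pdbx.get_structure(f, model=1)
            box = arr.box
        else:
            raise ValueError(f"unsupported structure format {fmt!r}")
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(f"{path}: malformed {fmt.upper()} file: {exc}") from exc

    structure = _from_atom_array(arr, box)
    sidecar = topology_sidecar_path(path)
    topology = FibrilTopology.load(sidecar) if sidecar.exists() else None
    return structure, topology


def write_structure(structure: Structure, path, topology: Optional[FibrilTopology] = None) -> None:
    """Write a Structure as PDB; a topology sidecar is written when given."""
    import biotite.structure.io.pdb as pdbio

    f = pdbio.PDBFile()
    f.set_structure(_to_atom_array(structure))
    f.write(str(path))
    if topology is not None:
        topology.save(topology_sidecar_path(path))


def write_trajectory_pdb(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    arrays = [_to_atom_array(frame) for frame in trajectory.frames()]
    stack = struc.stack(arrays)
    if arrays[0].box is not None:
        stack.box = np.stack([a.box for a in arrays])
    f = pdbio.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def write_trajectory_dcd(trajectory: Trajectory, path) -> None:
    """Write a trajectory as DCD (binary; scratch/exchange format)."""
    import MDAnalysis as mda

    n_atoms = trajectory.atoms.n_atoms
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with mda.coordinates.DCD.DCDWriter(str(path), n_atoms) as writer:
        for frame in trajectory.frames():
            u.atoms.positions = frame.coords.astype(np.float32)
            if frame.box is not None:
                u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
            writer.write(u.atoms)


class DCDTrajectory(Trajectory):
    """Lazily streamed DCD trajectory bound to a Structure atom table.

    Frames are produced one at a time from the reader; the full coordinate
    array is never materialized.
    """

    lazy = True

    def __init__(self, atoms: Structure, path):
        import MDAnalysis as mda

        self.atoms = atoms
        self.path = str(path)
        self._reader = mda.coordinates.DCD.DCDReader(self.path)
        if self._reader.n_atoms != atoms.n_atoms:
            raise ValueError(
                f"atom count mismatch: structure has {atoms.n_atoms} atoms, "
                f"trajectory has {self._reader.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self._reader.n_frames

    def frames(self) -> Iterator[Structure]:
        for ts in self._reader:
            box = None
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = np.asarray(ts.dimensions[:3], dtype=np.float64)
            yield self.atoms.with_coords(
                np.asarray(ts.positions, dtype=np.float64), box=box
            )


def read_trajectory(structure: Structure, path, fmt: Optional[str] = None) -> Trajectory:
    """Read a trajectory (DCD, streamed; or multi-model PDB, in memory).

    The structure supplies the atom table; its atom count must match the
    trajectory.
    """
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "dcd":
        return DCDTrajectory(structure, path)
    if fmt == "pdb":
        import biotite.structure.io.pdb as pdbio

        f = pdbio.PDBFile.read(str(path))
        stack = f.get_structure()
        coords = np.asarray(stack.coord, dtype=np.float64)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1] != structure.n_atoms:
            raise ValueError(
                f"atom count mismatch: structure has {structure.n_atoms} atoms, "
                f"trajectory has {coords.shape[1]}"
            )
        boxes = None
        if stack.box is not None:
            diags = np.diagonal(np.asarray(stack.box), axis1=-2, axis2=-1)
            if diags.ndim == 1:
                diags = np.tile(diags, (coords.shape[0], 1))
            if np.all(diags > 0):
                boxes = np.asarray(diags, dtype=np.float64)
        return InMemoryTrajectory(structure, coords, boxes)
    raise ValueError(f"unsupported trajectory format {fmt!r}")


def config_hash(config: dict) -> str:
    """Deterministic hash of a JSON-serializable run configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_manifest(path, command: str, inputs: dict, config: dict, seed: Optional[int] = None) -> dict:
    """Write a JSON run manifest making the result re-derivable.

    ``inputs`` maps role -> file path; files are content-hashed.
    """
    from . import __version__

    manifest = {
        "command": command,
        "inputs": {
            role: {"path": str(p), "sha256": _file_sha256(p) if Path(p).exists() else None}
            for role, p in inputs.items()
        },
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "version": __version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
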