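# chitofib

Construction and trajectory analysis of chitosan nanofibrils: crystallographic
fibril assembly, topologically classified hydrogen-bond statistics,
hydration and water-bridge observables, convex-hull volume change, and
dipole-orientation analysis — together with a synthetic-trajectory generator
that plants every parameter geometrically so each estimator can be validated
by ground-truth recovery.

## What it does

* **`chitofib.crystal`** — expands an asymmetric unit under orthorhombic
  screw-axis (P2₁2₁2₁-type) symmetry, tiles unit cells and assembles an
  oriented fibril (default: 4 antiparallel sheets × 6 chains × 20 glucosamine
  units, cell a=8.129, b=8.347, c=10.311 Å).  A packaged idealized glucosamine
  template means no external coordinates are needed; a real PDB/mmCIF
  asymmetric unit is an optional input.
* **`chitofib.hbonds`** — hydrogen-bond detection (donor–acceptor distance
  < 3.5 Å and donor–H–acceptor angle > 135°, minimum-image aware),
  classification into intra-chain / intra-sheet / inter-sheet /
  chitosan-water / water-water, prime-notation pair labels (e.g. `O3′H–O5`),
  occupancy tables and fraction-of-max series.
* **`chitofib.hydration`** — bound (< 3.5 Å) / bulk (≥ 10 Å) water
  assignment, interior-water counting between the two interior sheets,
  water-bridge detection (a water H-bonded to two chitosan atoms), and
  chitosan–water H-bond tables by donor/acceptor atom role.
* **`chitofib.geometry`** — convex-hull volume by explicit simplex
  tessellation (cross-checked against Qhull), ΔVolume series, end-to-end
  distance with contour bound, RMSF with best-fit superposition,
  sheet-stacking distance and sheet-growth dimension.
* **`chitofib.dipoles`** — partial-charge dipoles (μ = Σqᵢrᵢ, e·Å with Debye
  conversion), chain-dipole angles vs the chain vector, net fibril dipole
  (antiparallel cancellation), water dipole-orientation distributions and a
  Langevin maximum-likelihood κ estimator.
* **`chitofib.synthetic`** — trajectories with planted occupancies, stacking
  schedules, interior-water schedules, water bridges with survival
  probability, and κ-concentrated bulk-water dipoles; plus a paired
  field-off/field-on "dewetting scenario".
* **`chitofib.io` / `chitofib.cli`** — PDB/mmCIF reading (biotite), DCD
  streaming (MDAnalysis), JSON topology sidecars, tidy CSV output and run
  manifests.

## CLI

```sh
# build the default fibril (PDB + topology sidecar)
chitofib build --sheets 4 --chains 6 --dp 20 --cell 8.129,8.347,10.311 -o fibril.pdb

# generate the synthetic dewetting scenario (field-off + field-on)
chitofib simulate --seed 1 --frames 120 -o sim/

# run every analysis; writes tidy CSVs + a JSON run manifest
chitofib analyze all --traj sim/field_on.traj.pdb --top sim/field_on.pdb \
    --topology sim/topology.json -o results/

# summary tables and distribution plots
chitofib report -i results/ -o report/
```

Individual analyses are available as `analyze hbonds|hydration|geometry|dipoles`,
with criteria flags `--hb-dist 3.5 --hb-angle 135`.

## Library example

```python
from chitofib import build_fibril, SyntheticConfig, generate_trajectory
from chitofib.hbonds import occupancy

structure, topology = build_fibril()
cfg = SyntheticConfig(seed=1, n_frames=200, planted_occupancy={"N′H–O4": 0.8})
traj, truth = generate_trajectory(cfg, base=structure, topology=topology)
print(occupancy(traj, topology, pairs=["N′H–O4"]))
```
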