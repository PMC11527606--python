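# poregate

Analysis toolkit for gating and ion permeation in tetrameric ion-channel MD
trajectories, plus a synthetic toy-channel generator with planted,
manifest-recorded ground truth so every analysis is testable without running
MD.

What it computes:

- **Gating geometry** — per-frame gate aperture distances (mean of the two
  diagonal subunit-pair minimum distances, configurable), open/closed
  classification at a cutoff (default 5.69 Å, strict `>`), distributions and
  open fractions.
- **Permeation** — directional K⁺ crossing events through the selectivity
  filter, helix-bundle-crossing gate and G-loop gate, detected by a per-ion
  finite-state machine over compartment boundaries with hysteresis and a
  radial cutoff; per-region ion occupancy distributions and dwell-time
  profiles per region and per residue.
- **Interaction networks** — per-frame salt-bridge, hydrogen-bond and
  hydrophobic contacts, per-pair formed fractions over an analysis window,
  holo−apo difference tables, ranked largest changes, and ligand-contact
  percentages.
- **Collective dynamics** — Kabsch superposition, RMSD/RMSF, combined PCA
  over two concatenated ensembles (with mode-morph PDB export), Cα
  displacement cross-correlation matrices (DCCM) and their differences, and
  circular-statistics φ/ψ torsion summaries.
- **Synthetic channel** — a C4-symmetric bead-model channel whose gate
  apertures, scripted ion paths, contact formed-fractions, pair
  correlations and backbone dihedrals are planted exactly and recorded in a
  ground-truth manifest.

## Test

```
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact recovery of
planted ground truth plus the published worked example).

## CLI

Generate a synthetic system (writes `topology.pdb`, `traj.dcd`,
`manifest.json`):

```
poregate simulate --config sim.yaml --out simdir/
```

Run all configured analyses and comparisons:

```
poregate validate-config --config analysis.yaml
poregate analyze --config analysis.yaml
poregate compare --config analysis.yaml --apo APO_LABEL --holo HOLO_LABEL
```

An analysis config names the systems (label + topology + trajectory), the
gate/SF/ion/ligand selections, cutoffs, per-system frame windows, and the
ordered (apo, holo) comparisons; see `tests/test_pipeline.py::make_config`
for a complete example. Outputs are TSV tables and JSON summaries per
system, difference tables per comparison, and a `summary.json` with the
headline counts (permeation events, gate open fractions) and a config hash.

Selections use a small grammar: `chain A`, `resid 192`, `resid 3:5`,
`resname K`, `name CA`, the keywords `all`/`ion`/`ligand`/`protein`/
`backbone`, combined with `and`/`or`/`not` and parentheses.

## Conventions

Coordinates are Å; the pore axis is z with the extracellular side at larger
z; frames and atom indices are 0-based; residue numbers are kept as
authored. Residue identity is (chain, residue number, insertion code).
Alignment is always explicit (`principal_axis_align` or Kabsch
superposition), never applied silently. All randomness in the generator
flows from one integer seed through fixed substreams, and identical inputs
give byte-identical outputs.
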