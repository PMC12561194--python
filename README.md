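# pocketshaper

Ensemble analytics for engineering enzyme binding pockets and access
tunnels, built around the workflow used to redesign promiscuous
UDP-glycosyltransferases (UGTs) for regioselective glycosylation.

A microbial UGT with a spacious active site often binds its acceptor in
several competing orientations — tyrosol, for example, can present either
its alcoholic C8-OH or its phenolic C4-OH to the catalytic machinery,
yielding a near 1:1 mixture of salidroside and icariside D2. Engineering
such an enzyme means finding the few residues that stabilise *every*
productive binding state, mutating them, and verifying that the redesign
shifts the conformational statistics the right way. `pocketshaper`
implements the computational side of that loop for users who have (or
simulate) conformational ensembles:

- **Free-energy landscapes** — per-frame reaction coordinates (Kabsch RMSD,
  radius of gyration, or PCA projections) binned into
  ΔG(x, y) = −k_B T ln(P/P_max), with basin detection, merging and
  representative-frame extraction.
- **Interaction fingerprints & hotspots** — geometric detectors for
  hydrogen bonds, hydrophobic contacts, π–π stacks and π–ion contacts;
  per-residue contact frequencies per energy basin; selection of residues
  persistent in *all* basins (the mutagenesis shortlist), plus 5 Å-shell
  residue identification.
- **Pre-reaction-state (PRS) statistics** — for an inverting
  glycosyltransferase, the fraction of frames in which the acceptor oxygen
  is simultaneously within 3.5 Å of the catalytic histidine nitrogen and
  the UDP-glucose anomeric carbon, plus single-pair attack frequencies and
  distance distributions.
- **Tunnels & pockets** — centerline metrics (length, curvature = arc over
  chord, bottleneck, throughput = exp(−Σℓᵢ/rᵢ²)), a widest-path voxel-grid
  tunnel search, and flood-fill pocket volume/surface estimation.
- **Kinetics & library design** — Michaelis–Menten fitting (Hanes–Woolf
  initialised nonlinear least squares), kcat/Km reporting with printed-table
  rounding conventions, fold-changes, total turnover numbers, and exact NNK
  saturation-mutagenesis coverage statistics.
- **Synthetic systems** — a generator of toy enzyme–ligand ensembles with
  *exactly* planted basin occupancies, contact frequencies and PRS rates,
  so every stage can be validated against known ground truth.

## Worked example

`examples/01_free_energy_landscape.py` generates a 2000-frame two-basin
ensemble at 90%/10% occupancy and recovers the free-energy gap:

```
frames: 2000, occupied bins: 9
global basin at bin (7, 0): ΔG = -0.000 kcal/mol, 1650 member frames, representative frame 537
local  basin at bin (2, 7): ΔG = 1.327 kcal/mol, 178 member frames, representative frame 287
recovered ΔΔG = 1.327 kcal/mol (two-state expectation 1.310)
```

The recovered gap matches k_B·T·ln(0.9/0.1) = 1.310 kcal/mol up to one-bin
discretization error — the landscape reads back the planted thermodynamics.
`examples/02_hotspot_fingerprints.py` continues the workflow: six residues
planted persistent in both wells (contact frequencies 0.85/0.75) are
recovered exactly, while 0.30-frequency decoys are rejected:

```
selected hotspots (persistent in BOTH wells):
  A3    via hbond  frequencies 0.85/0.75
  A5    via hydrophobic  frequencies 0.85/0.75
  ...
planted hotspot set recovered exactly: True
```

`examples/05_kinetics_and_library.py` shows the reporting arithmetic: a
wild-type/variant pair with kcat/Km of 0.05 and 0.74 s⁻¹·mM⁻¹ is a 14.8×
efficiency gain, and screening 8 hotspot sites at 94 NNK clones each means
752 transformants versus 2162 for a whole 23-residue pocket. The other
examples cover PRS comparison, tunnel/pocket geometry and the end-to-end
YAML-driven workflow (also available as the `pocketshaper` CLI).

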