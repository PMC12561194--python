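# Methods

`pocketshaper` implements the computational scaffold used to re-engineer a
promiscuous UDP-glycosyltransferase toward regioselective glycosylation:
free-energy-landscape (FEL) analysis of conformational ensembles to locate
stable and metastable ligand-binding states, interaction-fingerprint (IFP)
statistics to find residues that persistently contact the acceptor in every
energy well (the mutagenesis hotspots), pre-reaction-state (PRS) statistics
that rationalise regioselectivity, tunnel and pocket geometry metrics for
access-path engineering, and the kinetics/library arithmetic used to report
the outcome. Because real molecular-dynamics trajectories of the system are
not reproducible at desk scale, every stage is validated against a
synthetic-ensemble generator with exactly planted statistics.

## Ensemble model and geometry

An ensemble is a fixed topology (atom name, element, residue number/name,
chain) plus T frames of N×3 coordinates in Å. Multi-model PDB is the
interchange format (read/written through biotite, one frame per MODEL).
Atom selections use a small expression language

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := (chain|resnum|resname|name) VALUE | "(" expr ")"

with `and` binding tighter than `or`; resolution is deterministic and
returns ascending atom indices.

RMSD between frames is the minimal root-mean-square deviation over proper
rigid motions (Kabsch superposition via scipy's `align_vectors`, which
excludes reflections — necessary for correctness on planar/2-atom
degenerate cases, which additionally raise a condition warning). The radius
of gyration is the mass-weighted RMS distance from the center of mass;
masses default to uniform. An equilibration detector returns the earliest
index from which every sliding-window mean stays within a tolerance of the
final window's mean; candidates must leave at least one full window before
the final one, so a still-drifting series is reported "not equilibrated"
(return value = series length).

## Free-energy landscapes

Two per-frame reaction coordinates (RMSD to a reference and radius of
gyration by default; the first two principal components of the superposed
coordinates as an alternative) are binned on a 2D histogram and converted
to relative free energy

    ΔG_ij = −k_B · T · ln(P_ij / P_max),   k_B = 0.0019872 kcal·mol⁻¹·K⁻¹,

zeroed at the most populated bin. Temperature defaults to 300 K and is an
explicit parameter. Empty bins are "unreachable" (+∞), never a finite ΔG.
Default binning is 40×40 with explicit edges overridable; the last bin is
right-closed. Basins are occupied bins strictly below all occupied
8-neighbors; candidates closer than a Chebyshev separation are merged
keeping the lower ΔG (ties broken lexicographically by bin index); the
lowest basin is "global", the others "local". A basin's representative
frame minimises the distance to the bin center in per-axis z-scored
coordinates (so Å-scale RMSD and Rg weigh equally); ties go to the lowest
frame index.

Choice of bin count for basin-gap recovery: the occupancy ratio of two
minima bins reflects the basin occupancy ratio only when each basin's
coordinate cloud is captured by about one bin. On the synthetic two-basin
systems the within-basin spread of both coordinates is ≈ 0.02–0.03 Å
against a basin separation of ≈ 0.5–0.7 Å, so 8×8 bins put each basin
inside roughly one bin and the recovered ΔΔG tracks k_B·T·ln(p₁/p₂) to
within a ±0.2 kcal·mol⁻¹ one-bin capture allowance (the worst case occurs
when a basin center falls near a bin edge and the peak bin captures only
part of the cloud). Finer grids trade this for larger capture noise.

## Interaction fingerprints and hotspots

Detectors are purely geometric; no topology is perceived:

| interaction | criterion | defaults |
|---|---|---|
| hydrogen bond | donor–acceptor heavy distance ≤ d, D–H…A angle ≥ α | 3.5 Å, 120° |
| hydrophobic | apolar C – apolar C distance ≤ d | 4.0 Å |
| π–π stack | ring-centroid distance ≤ d, interplanar angle ≤ α | 5.5 Å, 30° |
| π–ion | centroid→ion distance ≤ d, angle to ring normal ≤ α | 5.0 Å, 30° |

Hydrogens are attached to donors by a ≤ 1.2 Å distance heuristic; donors
without one fall back to the distance criterion alone and the event is
flagged `heavy_only`. An apolar carbon is a carbon with no N/O/S within
1.8 Å. Ring planes are least-squares fits of named ring selections (no
aromaticity perception). All cutoffs follow common interaction-fingerprint
practice, are configurable, and are carried on events for provenance.

A fingerprint counts a (residue, type) pair at most once per frame, so
frequencies are fractions of frames with the contact present. The 5 Å
shell uses a closed-boundary minimum-heavy-atom-distance criterion.
Hotspots are residues whose maximum-type frequency reaches a persistence
threshold (default 0.5 — a design choice, there is no canonical value) in
every basin, ranked by mean frequency, ties by residue number.

## Pre-reaction-state statistics

For an inverting glycosyltransferase the PRS requires the acceptor hydroxyl
oxygen simultaneously near the catalytic base nitrogen and the sugar
donor's anomeric carbon; operationally both distances strictly below
3.5 Å in the same frame. Frames exactly at the threshold are excluded and
counted in a diagnostic. The "attack frequency" is defined by this package
as the fraction of frames with a single pair distance strictly below the
same threshold (the literature uses the term qualitatively; every report
carries this definition string). Consequences asserted as invariants:
`prs_fraction ≤ min(attack frequencies)` and monotonicity in the
threshold. Distance comparisons between systems use the median, which is
robust to the long tails produced by unbound excursions.

## Tunnels and pockets

A tunnel profile is an ordered chain of centerline spheres. Derived
metrics: length (polyline arclength), curvature (arclength over end-to-end
chord, dimensionless ≥ 1; published tunnel tables sometimes print it with
an Å unit, which this package treats as a ratio), bottleneck (minimum
radius), cost `Σ ℓᵢ/rᵢ²` scaled by an explicit `cost_scale` (default 1),
and throughput `exp(−cost)`. The ℓ/r² integrand follows the convention of
widely used tunnel-analysis software in spirit; the absolute cost constant
of published throughput values is tool-specific and not recoverable, so no
claim is made of matching any particular printed throughput — only the
qualitative direction (shorter, straighter, wider ⇒ higher throughput) is
asserted, and it holds strictly for these formulas.

The tunnel search voxelises space (default 0.5 Å; per-element van der
Waals radii C 1.7, N 1.55, O 1.52, S/P 1.8 Å, probe 1.4 Å), marks voxels
free when clearance exceeds the probe radius, and runs a max-min
(widest-path) Dijkstra from the start voxel to the grid boundary with
deterministic tie-breaks; the returned bottleneck provably equals the
largest clearance threshold at which the start still connects to the
boundary, which is how tests validate it. Pocket volume is a flood fill of
free voxels from a seed, capped at the convex hull of the atom centers;
leakage through the hull flags the result "unbounded". Volume is voxel
count × spacing³; surface area counts pocket/protein faces × spacing² with
a 2/3 staircase correction (exact for a sphere in the fine-grid limit;
axis-aligned planar walls are under-counted — volume, not area, is the
primary pocket statistic).

## Kinetics and library design

Michaelis–Menten fits use nonlinear least squares (`scipy.curve_fit`,
tolerances 1e−12) initialised from the Hanes–Woolf linearisation, with
standard errors from the local curvature; `kcat = Vmax/[E]`. A flag warns
when `S_max < 2·Km` (poorly constrained Vmax). On a 0–7 mM substrate grid
noiseless data are recovered to machine precision for any positive
parameters with `S_max > Km/3`.

Catalytic efficiencies are reported raw and rounded half-up to 2 decimals,
and fold-changes at 1 decimal, because published tables print rounded
values and fold-changes recomputed from the rounded entries can differ
from unrounded ratios (e.g. 1.13/2.60 = 0.4346 rounds to 0.43 while the
corresponding printed efficiency is 0.44); both forms are always emitted.
TTN is product formed per enzyme in one consistent molar unit.

NNK single-site saturation (32 equiprobable codons; amino-acid
multiplicities 3× Leu/Arg/Ser, 2× Ala/Gly/Pro/Thr/Val, 1× the remaining
twelve, 1 stop) is modelled exactly: the coverage probability
P(all 20 amino acids in n draws) is an inclusion–exclusion sum grouped by
multiplicity class, and the clone requirement is the smallest n reaching a
confidence. At 95% the exact model requires 173 clones; the widely used
screening heuristic n = −V·ln(1−F) with V = 32 gives ≈ 96, and practical
protocols round to ≈ 94 clones per site — the package reports the exact
model alongside the coverage probability that ≈ 94 clones actually
achieves (≈ 52%), rather than silently adopting either convention.
Screening totals are plain products (sites × clones per site).

## Synthetic systems

The generator emulates the *statistical* structure of an enzyme–ligand
simulation, not its physics: a 24-residue × 4-atom pseudo-protein ring of
radius 12 Å around a pocket (residue 16 is the catalytic histidine
stand-in with an inward NE2 nitrogen), an 8-atom ligand (planar carbon
6-ring + two hydroxyl oxygens O4/O8), and a 3-atom donor fragment with a
labelled anomeric carbon. Two reference conformations (ring scaled ×1.06,
ligand shifted 0.8 Å) define the basins; frames are allocated to basins by
exact largest-remainder counts with a seeded shuffle and jittered
isotropically (σ = 0.12 Å default, small against the ≈ 0.5–0.7 Å basin
separation).

Contacts and PRS geometry are planted by exact counts, not Bernoulli
draws, so recovery tests have zero sampling slack: in "on" frames the
residue's probe atom is moved into a type-specific placement zone well
inside the detector cutoff (hydrogen-bond probes 2.6 Å from O4, out of
the ring plane; hydrophobic probes 1.85 Å radially outside their nearest
apolar ring carbon), and in "off" frames it stays at its distant reference
position. The zones are separated so a planted oxygen can never sit within
the 1.8 Å bond heuristic of a planted or ligand carbon and silently flip
its apolar classification. Plantable types are hydrogen bonds and
hydrophobic contacts — the two types the hotspot analysis aggregates; the
π-stack and π-ion detectors are validated on constructed ring geometries
instead, since the pseudo-residues carry no aromatic rings. PRS frames
place O8 at the midpoint of the anomeric carbon and catalytic nitrogen;
non-compliant frames are verified (and if necessary pushed) beyond 4.2 Å.

What passing these tests does and does not show: exact-count recovery
demonstrates that each statistic measures precisely what it claims on
ensembles whose labels are known; it does not show robustness to force
fields, solvent, sampling noise, or conformational heterogeneity beyond
two jittered basins — real trajectories have none of the generator's
crispness, and thresholds that recover planted labels exactly will sit on
continua in real data.

Michaelis–Menten data are generated on the 0–7 mM substrate grid used for
the published kinetics, with multiplicative Gaussian noise of configurable
coefficient of variation (5% in the noisy-recovery tests, a typical
initial-rate assay error).

## Problem sizes and numerics

Validation runs use 2000-frame ensembles (600 for the shared test
fixture), 8×8 FEL bins for gap recovery, 0.5 Å voxel grids (0.35 Å for
the convergence check), a 10⁶-trial Monte-Carlo oracle for NNK coverage,
and 200 seeded replicates for noisy kinetics recovery — sizes chosen so
each stage's statistical error is far below its test tolerance while the
whole suite runs in well under a minute. All randomness flows from
explicit integer seeds through numpy `default_rng`; workflows re-run with
the same config and seed produce byte-identical artifacts and a matching
content hash. Degenerate inputs (zero-variance FEL axes, coincident
tunnel endpoints, buried seeds, empty selections) raise typed errors with
the offending field named rather than propagating NaNs.
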