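"""Synthetic test systems with planted, exactly-controlled statistics.

The generators here stand in for molecular-dynamics trajectories of an
enzyme–ligand complex: a toy protein pocket with a ligand and a sugar-donor
fragment, sampled as a two-basin conformational ensemble with

* prescribed basin occupancies in (RMSD, Rg) space,
* per-residue contact patterns planted at prescribed persistence
  frequencies per basin, and
* a pre-reaction-state (dual-distance) geometry planted at a prescribed
  within-basin rate,

plus toy tunnel channels of prescribed radius profile and curvature, and
Michaelis–Menten rate tables with multiplicative noise.

All planting is by **exact counts** (largest-remainder rounding), not
Bernoulli draws, so downstream recovery tests carry zero sampling slack.
Every generator is a pure function of its spec, seed included.

Toy geometry (documented so planted-interaction placement is auditable):

* protein — 24 pseudo-residues of 4 atoms each (CA, CB1, CB2 and a polar
  OD1 oxygen) on a ring of radius 12 Å around the pocket; residue 16 is the
  catalytic histidine stand-in, its fourth atom being an NE2 nitrogen
  displaced toward the pocket centre;
* ligand (``TYL``) — 8 atoms: a planar 6-ring of carbons plus two hydroxyl
  oxygens ``O4`` (role "C4-OH-O") and ``O8`` (role "C8-OH-O");
* donor (``UPG``) — 3 atoms including the anomeric carbon ``C1``.

There is no physical realism (no sterics, no energetics); only the
statistical structure is controlled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Atom, AtomSelection, ConformationEnsemble, Frame, Topology, resolve_selection
from .channels import TunnelProfile

__all__ = [
    "PlantedContact",
    "EnsembleSpec",
    "ToyTunnelSpec",
    "RateDataSpec",
    "GroundTruth",
    "toy_topology",
    "toy_reference_frames",
    "default_two_basin_spec",
    "generate_two_basin_ensemble",
    "generate_toy_tunnel",
    "generate_rate_data",
    "largest_remainder_counts",
]

# Selections naming the toy system's special atoms
LIGAND_SEL = "resname TYL"
ACCEPTOR_O8_SEL = "resname TYL and name O8"
ACCEPTOR_O4_SEL = "resname TYL and name O4"
ANOMERIC_C_SEL = "resname UPG and name C1"
CATALYTIC_N_SEL = "resnum 16 and name NE2"

# Planting distances inside the detector cutoffs (Å).  "Off" frames simply
# leave the probe atom at its distant reference position, so no off-margin
# is needed.  Placement zones are separated by interaction type so that a
# planted oxygen probe can never sit within the 1.8 Å bond heuristic of a
# planted (or ligand) carbon and flip its apolar classification.
_HBOND_ON = 2.6        # probe O → ligand O4, out of the ring plane
_HYDROPHOBIC_ON = 1.85  # probe C → nearest apolar ring carbon, radially out
_PRS_OFF_MIN = 4.2     # non-compliant frames keep both key distances above this


@dataclass(frozen=True)
class PlantedContact:
    """One planted protein–ligand contact pattern.

    ``frequency`` is the fraction of that basin's frames in which the
    contact geometry is satisfied (exact count after rounding).
    """

    residue_key: tuple[str, int]
    interaction_type: str  # "hbond" | "hydrophobic"
    basin_id: int
    frequency: float

    def __post_init__(self):
        if self.interaction_type not in ("hbond", "hydrophobic"):
            raise ValueError(
                "plantable interaction types are 'hbond' and 'hydrophobic'; "
                f"got {self.interaction_type!r}"
            )
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must be in [0, 1]")


@dataclass(frozen=True)
class EnsembleSpec:
    n_frames: int
    basin_occupancies: tuple[float, ...]
    basin_reference_frames: tuple[Frame, ...]
    jitter_sigma: float = 0.12
    planted_contacts: tuple[PlantedContact, ...] = ()
    planted_prs: tuple[int, float] | None = None  # (basin_id, within-basin rate)
    prs_threshold: float = 3.5
    seed: int = 0

    def __post_init__(self):
        occ = np.asarray(self.basin_occupancies, dtype=float)
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError("basin occupancies must sum to 1")
        if np.any(occ < 0):
            raise ValueError("basin occupancies must be non-negative")
        if len(self.basin_reference_frames) != occ.size:
            raise ValueError("one reference frame per basin is required")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be ≥ 0")
        n0 = self.basin_reference_frames[0].coords.shape[0]
        for f in self.basin_reference_frames:
            if f.coords.shape[0] != n0:
                raise ValueError("reference frames have mismatched topology")
        if self.planted_prs is not None:
            b, rate = self.planted_prs
            if not 0 <= b < occ.size:
                raise ValueError("planted_prs basin_id out of range")
            if not 0.0 <= rate <= 1.0:
                raise ValueError("planted_prs rate must be in [0, 1]")


@dataclass(frozen=True)
class ToyTunnelSpec:
    """Parametric toy channel: ``("straight", length)``,
    ``("arc", R, theta_radians)`` or ``("polyline", points)``."""

    centerline: tuple
    radius_profile: tuple[float, ...]
    sphere_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.sphere_spacing <= 0:
            raise ValueError("sphere_spacing must be > 0")
        if any(r <= 0 for r in self.radius_profile):
            raise ValueError("all radii must be > 0")


@dataclass(frozen=True)
class RateDataSpec:
    km_mM: float
    kcat_per_s: float
    enzyme_conc: float
    substrate_grid_mM: tuple[float, ...]
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.km_mM <= 0 or self.kcat_per_s <= 0:
            raise ValueError("Km and kcat must be > 0")
        if len(self.substrate_grid_mM) < 4:
            raise ValueError("substrate grid needs ≥ 4 points")
        if any(s < 0 for s in self.substrate_grid_mM):
            raise ValueError("substrate concentrations must be ≥ 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be ≥ 0")


@dataclass
class GroundTruth:
    """Planted labels, sufficient to score every downstream stage."""

    basin_of_frame: list[int]
    occupancies: list[float]
    contact_frames: dict  # (chain, resnum, type, basin) -> sorted frame list
    contact_frequencies: dict  # same key -> planted frequency
    prs_frames: list[int]
    prs_rate: float | None
    prs_basin: int | None

    def basin_frames(self, basin_id: int) -> list[int]:
        return [t for t, b in enumerate(self.basin_of_frame) if b == basin_id]

    def to_json(self) -> str:
        def key_str(k):
            return "|".join(str(p) for p in k)

        payload = {
            "basin_of_frame": self.basin_of_frame,
            "occupancies": self.occupancies,
            "contact_frames": {key_str(k): v for k, v in self.contact_frames.items()},
            "contact_frequencies": {
                key_str(k): v for k, v in self.contact_frequencies.items()
            },
            "prs_frames": self.prs_frames,
            "prs_rate": self.prs_rate,
            "prs_basin": self.prs_basin,
        }
        return json.dumps(payload, indent=1)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


# ---------------------------------------------------------------------------
# Toy system construction
# ---------------------------------------------------------------------------

N_RESIDUES = 24
_RING_RADIUS = 12.0
_CATALYTIC_RESNUM = 16


def toy_topology() -> Topology:
    """24 pseudo-residues around a pocket + ligand (TYL) + donor (UPG)."""
    atoms: list[Atom] = []
    for i in range(N_RESIDUES):
        resnum = i + 1
        resname = "HIS" if resnum == _CATALYTIC_RESNUM else "ALA"
        fourth = ("NE2", "N") if resnum == _CATALYTIC_RESNUM else ("OD1", "O")
        for name, element in (("CA", "C"), ("CB1", "C"), ("CB2", "C"), fourth):
            atoms.append(Atom(name, element, resnum, resname, "A"))
    # ligand: planar 6-ring + two hydroxyl oxygens
    for name in ("C1L", "C2L", "C3L", "C4L", "C5L", "C6L"):
        atoms.append(Atom(name, "C", 101, "TYL", "L"))
    atoms.append(Atom("O4", "O", 101, "TYL", "L"))
    atoms.append(Atom("O8", "O", 101, "TYL", "L"))
    # donor fragment with labeled anomeric carbon
    atoms.append(Atom("C1", "C", 201, "UPG", "L"))
    atoms.append(Atom("O5", "O", 201, "UPG", "L"))
    atoms.append(Atom("PA", "P", 201, "UPG", "L"))
    return Topology(tuple(atoms))


def _toy_coords(ring_scale: float, ligand_shift: np.ndarray) -> np.ndarray:
    coords = []
    for i in range(N_RESIDUES):
        resnum = i + 1
        theta = 2.0 * np.pi * i / N_RESIDUES
        u = np.array([np.cos(theta), np.sin(theta), 0.0])  # outward unit vector
        ca = _RING_RADIUS * ring_scale * u
        cb1 = ca + 1.5 * u
        cb2 = ca + np.array([0.0, 0.0, 1.5])
        if resnum == _CATALYTIC_RESNUM:
            fourth = ca - 2.8 * u  # NE2 points into the pocket
        else:
            fourth = ca - np.array([0.0, 0.0, 1.5])
        coords.extend([ca, cb1, cb2, fourth])
    # ligand ring (radius 1.4 Å) in the xy-plane near the pocket centre
    center = np.array([0.0, 0.0, 0.0]) + ligand_shift
    for k in range(6):
        phi = 2.0 * np.pi * k / 6
        coords.append(center + 1.4 * np.array([np.cos(phi), np.sin(phi), 0.0]))
    ring = coords[-6:]
    coords.append(ring[0] + 1.4 * (ring[0] - center) / np.linalg.norm(ring[0] - center))  # O4
    coords.append(ring[3] + 1.4 * (ring[3] - center) / np.linalg.norm(ring[3] - center))  # O8
    # donor near the catalytic nitrogen's inward direction
    theta16 = 2.0 * np.pi * (_CATALYTIC_RESNUM - 1) / N_RESIDUES
    u16 = np.array([np.cos(theta16), np.sin(theta16), 0.0])
    c1 = 6.5 * u16
    coords.append(c1)                      # C1 (anomeric)
    coords.append(c1 + np.array([0.0, 0.0, 1.4]))  # O5
    coords.append(c1 + 1.6 * u16)          # PA
    return np.asarray(coords)


def toy_reference_frames() -> tuple[Frame, Frame]:
    """Two reference conformations differing in ring radius and ligand pose,
    giving well-separated (RMSD, Rg) basins under small jitter."""
    a = Frame(_toy_coords(1.0, np.zeros(3)), frame_index=0)
    b = Frame(_toy_coords(1.06, np.array([0.8, 0.0, 0.0])), frame_index=0)
    return a, b


def default_two_basin_spec(
    n_frames: int = 2000,
    occupancies: Sequence[float] = (0.75, 0.25),
    jitter_sigma: float = 0.12,
    planted_contacts: Sequence[PlantedContact] = (),
    planted_prs: tuple[int, float] | None = (0, 0.30),
    seed: int = 0,
) -> EnsembleSpec:
    ref_a, ref_b = toy_reference_frames()
    return EnsembleSpec(
        n_frames=n_frames,
        basin_occupancies=tuple(float(p) for p in occupancies),
        basin_reference_frames=(ref_a, ref_b),
        jitter_sigma=jitter_sigma,
        planted_contacts=tuple(planted_contacts),
        planted_prs=planted_prs,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Planting helpers
# ---------------------------------------------------------------------------

def largest_remainder_counts(probabilities: Sequence[float], total: int) -> np.ndarray:
    """Integer allocation of ``total`` across categories, largest-remainder
    rounding, ties broken by category index."""
    p = np.asarray(probabilities, dtype=float)
    raw = p * total
    base = np.floor(raw).astype(int)
    remainder = int(total - base.sum())
    order = np.lexsort((np.arange(p.size), -(raw - base)))
    base[order[:remainder]] += 1
    return base


def _round_count(frequency: float, n: int) -> int:
    return int(np.floor(frequency * n + 0.5))


def _single_index(topology: Topology, expression: str) -> int:
    sel = resolve_selection(topology, expression)
    if len(sel) != 1:
        raise ValueError(f"selection {expression!r} must resolve to one atom")
    return sel.resolved_indices[0]


def generate_two_basin_ensemble(
    spec: EnsembleSpec, topology: Topology | None = None
) -> tuple[ConformationEnsemble, GroundTruth]:
    """Sample a two-(or k-)basin ensemble with planted statistics.

    Frames are allocated to basins by exact largest-remainder counts and a
    seeded shuffle, jittered isotropically around the basin reference, and
    then planted contacts / pre-reaction-state geometry are imposed by
    moving the involved probe atoms to distances safely inside (or outside)
    the detector cutoffs.  The returned :class:`GroundTruth` stores every
    planted label per frame.
    """
    topo = topology if topology is not None else toy_topology()
    n_atoms = topo.n_atoms
    for f in spec.basin_reference_frames:
        if f.coords.shape[0] != n_atoms:
            raise ValueError("reference frames have mismatched topology")

    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    counts = largest_remainder_counts(spec.basin_occupancies, n)
    perm = rng.permutation(n)
    basin_of_frame = np.empty(n, dtype=int)
    start = 0
    for b, c in enumerate(counts):
        basin_of_frame[perm[start : start + c]] = b
        start += c

    refs = [np.asarray(f.coords, dtype=float) for f in spec.basin_reference_frames]
    coords = np.empty((n, n_atoms, 3))
    for t in range(n):
        coords[t] = refs[basin_of_frame[t]] + rng.normal(
            0.0, spec.jitter_sigma, size=(n_atoms, 3)
        )

    by_key: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(topo.atoms):
        by_key.setdefault(a.residue_key, []).append(i)

    o4 = _single_index(topo, ACCEPTOR_O4_SEL)
    o8 = _single_index(topo, ACCEPTOR_O8_SEL)
    c1 = _single_index(topo, ANOMERIC_C_SEL)
    ne2 = _single_index(topo, CATALYTIC_N_SEL)
    # apolar ring carbons = hydrophobic planting anchors (the two ring
    # carbons bearing hydroxyls are polar by the bond heuristic)
    apolar_ring = [
        _single_index(topo, f"resname TYL and name {nm}")
        for nm in ("C2L", "C3L", "C5L", "C6L")
    ]
    ring_all = [
        _single_index(topo, f"resname TYL and name {nm}")
        for nm in ("C1L", "C2L", "C3L", "C4L", "C5L", "C6L")
    ]

    contact_frames: dict = {}
    contact_freqs: dict = {}
    for pc in spec.planted_contacts:
        if pc.residue_key not in by_key:
            raise ValueError(f"planted residue {pc.residue_key} not in topology")
        basin_frames = np.flatnonzero(basin_of_frame == pc.basin_id)
        n_on = _round_count(pc.frequency, basin_frames.size)
        on = np.sort(rng.permutation(basin_frames)[:n_on])
        atoms_idx = by_key[pc.residue_key]
        names = {topo.atoms[i].atom_name: i for i in atoms_idx}
        resnum = pc.residue_key[1]
        if pc.interaction_type == "hbond":
            probe = names.get("OD1", names.get("NE2"))
            if probe is None:
                raise ValueError(f"residue {pc.residue_key} has no polar probe atom")
        else:
            probe = names["CB1"]
        ca = names["CA"]
        for t in on:
            ca_pos = coords[t, ca]
            if pc.interaction_type == "hbond":
                # above/below the ligand O4, tilted toward the residue:
                # 2.6 Å from O4, ≥ ~2.9 Å from every ring carbon
                tgt = coords[t, o4]
                azim = ca_pos - tgt
                azim[2] = 0.0
                azim /= max(np.linalg.norm(azim), 1e-9)
                z_sign = 1.0 if resnum % 2 == 0 else -1.0
                direction = 0.12 * azim + np.array([0.0, 0.0, z_sign])
                direction /= np.linalg.norm(direction)
                coords[t, probe] = tgt + _HBOND_ON * direction
            else:
                # radially outside the nearest apolar ring carbon, with an
                # alternating out-of-plane nudge to avoid probe coincidence
                center = coords[t, ring_all].mean(axis=0)
                anchor = min(
                    apolar_ring,
                    key=lambda i: np.linalg.norm(coords[t, i] - ca_pos),
                )
                u = coords[t, anchor] - center
                u[2] = 0.0
                u /= max(np.linalg.norm(u), 1e-9)
                z_off = 0.3 if resnum % 2 == 0 else -0.3
                coords[t, probe] = (
                    coords[t, anchor]
                    + _HYDROPHOBIC_ON * u
                    + np.array([0.0, 0.0, z_off])
                )
        key = (pc.residue_key[0], pc.residue_key[1], pc.interaction_type, pc.basin_id)
        contact_frames[key] = [int(t) for t in on]
        contact_freqs[key] = pc.frequency

    prs_frames: list[int] = []
    prs_rate = None
    prs_basin = None
    if spec.planted_prs is not None:
        prs_basin, prs_rate = spec.planted_prs
        basin_frames = np.flatnonzero(basin_of_frame == prs_basin)
        n_on = _round_count(prs_rate, basin_frames.size)
        on = np.sort(rng.permutation(basin_frames)[:n_on])
        on_set = set(int(t) for t in on)
        thr = spec.prs_threshold
        for t in range(n):
            mid = 0.5 * (coords[t, c1] + coords[t, ne2])
            gap = np.linalg.norm(coords[t, c1] - coords[t, ne2])
            if int(t) in on_set:
                if gap / 2.0 >= thr - 0.3:
                    raise ValueError(
                        "anomeric carbon and catalytic nitrogen are too far "
                        "apart to plant a compliant pre-reaction state"
                    )
                coords[t, o8] = mid
            else:
                # ensure at least one key distance stays safely non-compliant
                d1 = np.linalg.norm(coords[t, o8] - coords[t, c1])
                d2 = np.linalg.norm(coords[t, o8] - coords[t, ne2])
                if d1 < _PRS_OFF_MIN and d2 < _PRS_OFF_MIN:
                    away = coords[t, o8] - mid
                    norm = np.linalg.norm(away)
                    away = away / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
                    coords[t, o8] = mid + (_PRS_OFF_MIN + thr) * away
        prs_frames = [int(t) for t in on]

    frames = tuple(Frame(coords=coords[t], frame_index=t) for t in range(n))
    ensemble = ConformationEnsemble(topology=topo, frames=frames)
    truth = GroundTruth(
        basin_of_frame=[int(b) for b in basin_of_frame],
        occupancies=[float(p) for p in spec.basin_occupancies],
        contact_frames=contact_frames,
        contact_frequencies=contact_freqs,
        prs_frames=prs_frames,
        prs_rate=prs_rate,
        prs_basin=prs_basin,
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# Toy tunnels and kinetics data
# ---------------------------------------------------------------------------

def _centerline_points(spec: ToyTunnelSpec) -> np.ndarray:
    kind = spec.centerline[0]
    h = spec.sphere_spacing
    if kind == "straight":
        length = float(spec.centerline[1])
        n = int(np.floor(length / h + 1e-9)) + 1
        z = np.linspace(0.0, length, n)
        return np.column_stack([np.zeros(n), np.zeros(n), z])
    if kind == "arc":
        radius, theta = float(spec.centerline[1]), float(spec.centerline[2])
        arc_len = radius * theta
        n = max(2, int(np.round(arc_len / h)) + 1)
        ang = np.linspace(0.0, theta, n)
        return np.column_stack(
            [radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)]
        )
    if kind == "polyline":
        pts = np.asarray(spec.centerline[1], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("polyline needs ≥ 2 three-dimensional points")
        # resample at uniform arclength spacing
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(2, int(np.round(s[-1] / h)) + 1)
        si = np.linspace(0.0, s[-1], n)
        return np.column_stack([np.interp(si, s, pts[:, k]) for k in range(3)])
    raise ValueError(f"unknown centerline kind {kind!r}")


def generate_toy_tunnel(spec: ToyTunnelSpec) -> TunnelProfile:
    """Centerline spheres sampled along the parametric curve.

    The radius profile is linearly interpolated along arclength when its
    length differs from the sphere count.  Deterministic for a given spec.
    """
    centers = _centerline_points(spec)
    n = centers.shape[0]
    prof = np.asarray(spec.radius_profile, dtype=float)
    if prof.size == n:
        radii = prof
    elif prof.size == 1:
        radii = np.full(n, prof[0])
    else:
        radii = np.interp(
            np.linspace(0.0, 1.0, n), np.linspace(0.0, 1.0, prof.size), prof
        )
    return TunnelProfile(
        spheres=tuple((tuple(c), float(r)) for c, r in zip(centers, radii)),
        label=f"toy-{spec.centerline[0]}",
    )


def generate_rate_data(spec: RateDataSpec) -> pd.DataFrame:
    """Initial-rate table ``(substrate_mM, rate)`` from the Michaelis–Menten
    law with seeded multiplicative Gaussian noise:
    ``v = kcat·E·S/(Km+S) · (1 + ε)``, ``ε ~ N(0, noise_cv)``."""
    rng = np.random.default_rng(spec.seed)
    s = np.asarray(spec.substrate_grid_mM, dtype=float)
    v = spec.kcat_per_s * spec.enzyme_conc * s / (spec.km_mM + s)
    if spec.noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, spec.noise_cv, size=s.size))
    return pd.DataFrame({"substrate_mM": s, "rate": v})
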