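"""Geometric protein–ligand interaction detection and fingerprints.

Detectors implement standard distance/angle criteria for hydrogen bonds,
hydrophobic contacts, π–π stacking and π–ion contacts.  No topology is
perceived: hydrogens are attached to donors by a ≤ 1.2 Å distance
heuristic (with a flagged heavy-atom-only fallback when absent), apolar
carbons are carbons with no N/O/S within 1.8 Å, and aromatic rings are
supplied as named atom selections.

An :class:`InteractionFingerprint` aggregates events into per-residue,
per-type contact *frequencies* over an ensemble (or a basin's frames): a
residue–type pair counts at most once per frame, so a frequency is the
fraction of frames in which the contact is present.  Residues persistently
contacting the ligand in every energy basin are the engineering hotspots.

All geometric cutoffs are configuration defaults following common
interaction-fingerprint practice and are carried on every event for
provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomSelection, ConformationEnsemble, Frame, Topology

__all__ = [
    "ContactConfig",
    "InteractionEvent",
    "InteractionFingerprint",
    "shell_residues",
    "detect_hbonds",
    "detect_hydrophobic",
    "detect_pi_stack",
    "detect_pi_ion",
    "fingerprint",
    "select_hotspots",
]


@dataclass(frozen=True)
class ContactConfig:
    shell_radius: float = 5.0
    hbond_dist: float = 3.5
    hbond_angle: float = 120.0
    hydrophobic_dist: float = 4.0
    pi_centroid_dist: float = 5.5
    pi_plane_angle: float = 30.0
    pi_ion_dist: float = 5.0
    pi_ion_axis_angle: float = 30.0

    def __post_init__(self):
        for name in (
            "shell_radius",
            "hbond_dist",
            "hydrophobic_dist",
            "pi_centroid_dist",
            "pi_ion_dist",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_angle", "pi_plane_angle", "pi_ion_axis_angle"):
            a = getattr(self, name)
            if not 0 < a <= 180:
                raise ValueError(f"{name} must be in (0, 180]")


@dataclass(frozen=True)
class InteractionEvent:
    frame_index: int
    residue_key: tuple[str, int]
    interaction_type: str  # hbond | hydrophobic | pi_stack | pi_ion
    atoms: tuple[int, ...]
    distance: float
    angle: float | None = None
    heavy_only: bool = False  # hbond detected without a resolvable hydrogen


@dataclass(frozen=True)
class InteractionFingerprint:
    frequencies: Mapping[tuple[tuple[str, int], str], float]
    n_frames: int
    scope: str = "ensemble"

    def frequency(self, residue_key: tuple[str, int], interaction_type: str) -> float:
        return self.frequencies.get((residue_key, interaction_type), 0.0)

    def max_type_frequency(self, residue_key: tuple[str, int]) -> float:
        vals = [
            f for (rk, _), f in self.frequencies.items() if rk == residue_key
        ]
        return max(vals) if vals else 0.0

    def residues(self) -> list[tuple[str, int]]:
        return sorted({rk for rk, _ in self.frequencies}, key=lambda k: (k[0], k[1]))


# ---------------------------------------------------------------------------
# Atom classification helpers (distance-heuristic, no bond perception)
# ---------------------------------------------------------------------------

def _heavy_mask(topology: Topology) -> np.ndarray:
    return np.array([a.element != "H" for a in topology.atoms])


def _apolar_carbon_mask(frame: Frame, topology: Topology) -> np.ndarray:
    """Carbon not within 1.8 Å (bond heuristic) of any N/O/S atom."""
    elements = np.array([a.element for a in topology.atoms])
    carbons = elements == "C"
    polar = np.isin(elements, ("N", "O", "S"))
    mask = carbons.copy()
    if polar.any() and carbons.any():
        tree = cKDTree(frame.coords[polar])
        d, _ = tree.query(frame.coords[carbons], k=1)
        mask[np.flatnonzero(carbons)[d <= 1.8]] = False
    return mask


def _attached_hydrogens(
    frame: Frame, topology: Topology, donor_idx: int
) -> list[int]:
    out = []
    for i, a in enumerate(topology.atoms):
        if a.element == "H" and np.linalg.norm(
            frame.coords[i] - frame.coords[donor_idx]
        ) <= 1.2:
            out.append(i)
    return out


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u = a - vertex
    v = b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def shell_residues(
    frame: Frame,
    topology: Topology,
    ligand: AtomSelection,
    radius: float = 5.0,
) -> set[tuple[str, int]]:
    """Residues with any non-ligand heavy atom within ``radius`` (closed
    boundary, minimum-distance criterion) of any ligand heavy atom."""
    if ligand.is_empty:
        raise ValueError("ligand selection is empty")
    heavy = _heavy_mask(topology)
    lig = np.zeros(topology.n_atoms, dtype=bool)
    lig[list(ligand.resolved_indices)] = True
    lig_idx = np.flatnonzero(lig & heavy)
    other_idx = np.flatnonzero(~lig & heavy)
    if lig_idx.size == 0 or other_idx.size == 0:
        return set()
    tree = cKDTree(frame.coords[lig_idx])
    d, _ = tree.query(frame.coords[other_idx], k=1)
    out: set[tuple[str, int]] = set()
    for i, dist in zip(other_idx, d):
        if dist <= radius:
            out.add(topology.atoms[i].residue_key)
    return out


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    donors: AtomSelection,
    acceptors: AtomSelection,
    config: ContactConfig = ContactConfig(),
) -> list[InteractionEvent]:
    """Hydrogen bonds: donor–acceptor heavy distance ≤ cutoff and
    D–H…A angle ≥ cutoff; falls back to the distance criterion alone
    (``heavy_only`` flagged) for donors with no attached hydrogen."""
    events = []
    for d_idx in donors.resolved_indices:
        hydrogens = _attached_hydrogens(frame, topology, d_idx)
        for a_idx in acceptors.resolved_indices:
            if a_idx == d_idx:
                continue
            dist = float(
                np.linalg.norm(frame.coords[d_idx] - frame.coords[a_idx])
            )
            if dist > config.hbond_dist:
                continue
            if hydrogens:
                best = max(
                    _angle_deg(
                        frame.coords[d_idx],
                        frame.coords[h],
                        frame.coords[a_idx],
                    )
                    for h in hydrogens
                )
                if best < config.hbond_angle:
                    continue
                events.append(
                    InteractionEvent(
                        frame_index=frame.frame_index,
                        residue_key=topology.atoms[d_idx].residue_key,
                        interaction_type="hbond",
                        atoms=(d_idx, a_idx),
                        distance=dist,
                        angle=best,
                    )
                )
            else:
                events.append(
                    InteractionEvent(
                        frame_index=frame.frame_index,
                        residue_key=topology.atoms[d_idx].residue_key,
                        interaction_type="hbond",
                        atoms=(d_idx, a_idx),
                        distance=dist,
                        heavy_only=True,
                    )
                )
    return events


def detect_hydrophobic(
    frame: Frame,
    topology: Topology,
    ligand: AtomSelection,
    config: ContactConfig = ContactConfig(),
) -> list[InteractionEvent]:
    """Apolar residue carbon within the cutoff of an apolar ligand carbon."""
    apolar = _apolar_carbon_mask(frame, topology)
    lig = np.zeros(topology.n_atoms, dtype=bool)
    lig[list(ligand.resolved_indices)] = True
    lig_c = np.flatnonzero(lig & apolar)
    prot_c = np.flatnonzero(~lig & apolar)
    events = []
    if lig_c.size == 0 or prot_c.size == 0:
        return events
    tree = cKDTree(frame.coords[lig_c])
    pairs = tree.query_ball_point(frame.coords[prot_c], r=config.hydrophobic_dist)
    for pi, hits in zip(prot_c, pairs):
        for h in hits:
            li = lig_c[h]
            dist = float(np.linalg.norm(frame.coords[pi] - frame.coords[li]))
            events.append(
                InteractionEvent(
                    frame_index=frame.frame_index,
                    residue_key=topology.atoms[pi].residue_key,
                    interaction_type="hydrophobic",
                    atoms=(int(pi), int(li)),
                    distance=dist,
                )
            )
    return events


def _ring_centroid_normal(frame: Frame, ring: AtomSelection) -> tuple[np.ndarray, np.ndarray]:
    pts = frame.coords[list(ring.resolved_indices)]
    if pts.shape[0] < 3:
        raise ValueError("a ring selection needs ≥ 3 atoms")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[2]  # least-squares plane normal


def detect_pi_stack(
    frame: Frame,
    topology: Topology,
    ring_a: AtomSelection,
    ring_b: AtomSelection,
    config: ContactConfig = ContactConfig(),
) -> list[InteractionEvent]:
    """Parallel π–π stacking: centroid distance ≤ cutoff and interplanar
    angle ≤ cutoff (face-to-face only; perpendicular rings do not count)."""
    ca, na = _ring_centroid_normal(frame, ring_a)
    cb, nb = _ring_centroid_normal(frame, ring_b)
    dist = float(np.linalg.norm(ca - cb))
    if dist > config.pi_centroid_dist:
        return []
    cosang = abs(float(np.dot(na, nb)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    if angle > config.pi_plane_angle:
        return []
    first = ring_a.resolved_indices[0]
    return [
        InteractionEvent(
            frame_index=frame.frame_index,
            residue_key=topology.atoms[first].residue_key,
            interaction_type="pi_stack",
            atoms=tuple(ring_a.resolved_indices) + tuple(ring_b.resolved_indices),
            distance=dist,
            angle=angle,
        )
    ]


def detect_pi_ion(
    frame: Frame,
    topology: Topology,
    ring: AtomSelection,
    ion_group: AtomSelection,
    config: ContactConfig = ContactConfig(),
) -> list[InteractionEvent]:
    """π–ion contact: ring-centroid → ion distance ≤ cutoff and the angle
    between the ring normal and the centroid→ion vector ≤ cutoff (the ion
    sits over the ring face, not in its plane)."""
    centroid, normal = _ring_centroid_normal(frame, ring)
    events = []
    for i_idx in ion_group.resolved_indices:
        v = frame.coords[i_idx] - centroid
        dist = float(np.linalg.norm(v))
        if dist > config.pi_ion_dist or dist < 1e-9:
            continue
        cosang = abs(float(np.dot(normal, v / dist)))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if angle > config.pi_ion_axis_angle:
            continue
        events.append(
            InteractionEvent(
                frame_index=frame.frame_index,
                residue_key=topology.atoms[i_idx].residue_key,
                interaction_type="pi_ion",
                atoms=tuple(ring.resolved_indices) + (i_idx,),
                distance=dist,
                angle=angle,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Fingerprint aggregation and hotspot selection
# ---------------------------------------------------------------------------

def _polar_selection(topology: Topology, indices: Iterable[int]) -> AtomSelection:
    polar = tuple(
        i for i in indices if topology.atoms[i].element in ("N", "O")
    )
    return AtomSelection(expression="<polar>", resolved_indices=polar)


def fingerprint(
    ensemble: ConformationEnsemble,
    ligand: AtomSelection,
    config: ContactConfig = ContactConfig(),
    frame_indices: Sequence[int] | None = None,
    scope: str = "ensemble",
) -> InteractionFingerprint:
    """Per-residue, per-type contact frequencies over frames.

    Hydrogen bonds are evaluated in both donor directions (protein N/O vs
    ligand N/O); hydrophobic contacts between apolar carbons.  A residue–
    type pair counts at most once per frame, so every frequency is the
    fraction of frames in which at least one qualifying event exists.
    """
    topo = ensemble.topology
    if frame_indices is None:
        frames = list(ensemble.frames)
    else:
        by_index = {f.frame_index: f for f in ensemble.frames}
        frames = [by_index[t] for t in frame_indices]
    if not frames:
        raise ValueError("no frames in scope")
    lig_set = set(ligand.resolved_indices)
    prot_idx = [i for i in range(topo.n_atoms) if i not in lig_set]
    prot_polar = _polar_selection(topo, prot_idx)
    lig_polar = _polar_selection(topo, ligand.resolved_indices)

    present: dict[tuple[tuple[str, int], str], int] = {}
    for frame in frames:
        seen: set[tuple[tuple[str, int], str]] = set()
        events: list[InteractionEvent] = []
        if not prot_polar.is_empty and not lig_polar.is_empty:
            events += detect_hbonds(frame, topo, prot_polar, lig_polar, config)
            # ligand as donor: attribute the event to the protein residue
            for ev in detect_hbonds(frame, topo, lig_polar, prot_polar, config):
                acc = ev.atoms[1]
                events.append(
                    InteractionEvent(
                        frame_index=ev.frame_index,
                        residue_key=topo.atoms[acc].residue_key,
                        interaction_type="hbond",
                        atoms=ev.atoms,
                        distance=ev.distance,
                        angle=ev.angle,
                        heavy_only=ev.heavy_only,
                    )
                )
        events += detect_hydrophobic(frame, topo, ligand, config)
        for ev in events:
            key = (ev.residue_key, ev.interaction_type)
            if key not in seen:
                seen.add(key)
                present[key] = present.get(key, 0) + 1

    n = len(frames)
    freqs = {k: c / n for k, c in present.items()}
    return InteractionFingerprint(frequencies=freqs, n_frames=n, scope=scope)


def select_hotspots(
    fingerprints_by_basin: Mapping[object, InteractionFingerprint],
    min_frequency: float = 0.5,
    require_all_basins: bool = True,
) -> list[tuple[tuple[str, int], tuple[str, ...], dict]]:
    """Residues persistently contacting the ligand across energy basins.

    A residue qualifies when its maximum-type frequency reaches
    ``min_frequency`` in every basin (or in at least one, when
    ``require_all_basins`` is False).  Ranked by mean max-type frequency
    descending; ties by residue number ascending.  Each entry is
    ``(residue_key, supporting interaction types, per-basin frequencies)``.
    """
    if not fingerprints_by_basin:
        raise ValueError("at least one basin fingerprint is required")
    all_residues: set[tuple[str, int]] = set()
    for fp in fingerprints_by_basin.values():
        all_residues.update(fp.residues())

    rows = []
    for rk in all_residues:
        per_basin = {
            b: fp.max_type_frequency(rk) for b, fp in fingerprints_by_basin.items()
        }
        hits = [f >= min_frequency for f in per_basin.values()]
        ok = all(hits) if require_all_basins else any(hits)
        if not ok:
            continue
        types = sorted(
            {
                t
                for fp in fingerprints_by_basin.values()
                for (r, t), f in fp.frequencies.items()
                if r == rk and f >= min_frequency
            }
        )
        mean_freq = float(np.mean(list(per_basin.values())))
        rows.append((rk, tuple(types), per_basin, mean_freq))

    rows.sort(key=lambda r: (-r[3], r[0][1]))
    return [(rk, types, per_basin) for rk, types, per_basin, _ in rows]
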