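"""Interaction detectors, fingerprint frequencies and hotspot selection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pocketshaper as ps
from pocketshaper.core import Atom, AtomSelection, Frame, Topology, resolve_selection
from pocketshaper.interactions import (
    ContactConfig,
    InteractionFingerprint,
    detect_hbonds,
    detect_hydrophobic,
    detect_pi_ion,
    detect_pi_stack,
    fingerprint,
    select_hotspots,
    shell_residues,
)


def _topo(atoms):
    return Topology(tuple(Atom(*a) for a in atoms))


def _hexagon(center, radius=1.4, normal_z=True):
    pts = []
    for k in range(6):
        phi = 2 * np.pi * k / 6
        pts.append(center + radius * np.array([np.cos(phi), np.sin(phi), 0.0]))
    return np.array(pts)


class TestShellResidues:
    def _system(self, d):
        """One ligand atom at origin, one residue atom at distance d."""
        topo = _topo(
            [
                ("C1", "C", 1, "LIG", "L"),
                ("CA", "C", 2, "ALA", "A"),
            ]
        )
        frame = Frame(np.array([[0.0, 0, 0], [d, 0, 0]]))
        lig = AtomSelection("lig", (0,))
        return topo, frame, lig

    def test_inside_boundary_included(self):
        topo, frame, lig = self._system(4.9)
        assert shell_residues(frame, topo, lig, 5.0) == {("A", 2)}

    def test_outside_boundary_excluded(self):
        topo, frame, lig = self._system(5.1)
        assert shell_residues(frame, topo, lig, 5.0) == set()

    def test_planted_pocket_matches_brute_force(self, planted_ensemble):
        ens, _ = planted_ensemble
        topo = ens.topology
        lig = resolve_selection(topo, "resname TYL")
        frame = ens.frames[0]
        got = shell_residues(frame, topo, lig, 5.0)
        lig_idx = set(lig.resolved_indices)
        expected = set()
        for i, a in enumerate(topo.atoms):
            if i in lig_idx or a.element == "H":
                continue
            d = np.linalg.norm(
                frame.coords[list(lig_idx)] - frame.coords[i], axis=1
            ).min()
            if d <= 5.0:
                expected.add(a.residue_key)
        assert got == expected


class TestHbondDetector:
    def _system(self, d_pos, h_pos=None, a_pos=(2.9, 0, 0)):
        atoms = [("OD1", "O", 1, "ASP", "A"), ("O1", "O", 9, "LIG", "L")]
        coords = [list(d_pos), list(a_pos)]
        if h_pos is not None:
            atoms.insert(1, ("HD1", "H", 1, "ASP", "A"))
            coords.insert(1, list(h_pos))
        topo = _topo(atoms)
        frame = Frame(np.array(coords, dtype=float))
        donors = AtomSelection("d", (0,))
        acceptors = AtomSelection("a", (len(atoms) - 1,))
        return topo, frame, donors, acceptors

    def test_good_geometry_detected(self):
        # D at origin, H on the D→A axis: angle 180° ≥ 120°, distance 2.9
        topo, frame, d, a = self._system((0, 0, 0), (1.0, 0, 0))
        events = detect_hbonds(frame, topo, d, a)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(2.9)
        assert not events[0].heavy_only

    def test_long_distance_rejected(self):
        topo, frame, d, a = self._system((0, 0, 0), (1.0, 0, 0), a_pos=(3.6, 0, 0))
        assert detect_hbonds(frame, topo, d, a) == []

    def test_bad_angle_rejected(self):
        # H at (0.5, 0.87, 0) puts the D–H…A angle near 100°, below 120°
        topo, frame, d, a = self._system((0, 0, 0), (0.5, 0.87, 0.0))
        events = detect_hbonds(frame, topo, d, a)
        assert events == []

    def test_heavy_only_fallback_flagged(self):
        topo, frame, d, a = self._system((0, 0, 0))
        events = detect_hbonds(frame, topo, d, a)
        assert len(events) == 1 and events[0].heavy_only


class TestHydrophobicDetector:
    def _system(self, protein_atom, d):
        atoms = [
            (protein_atom[0], protein_atom[1], 1, "LEU", "A"),
            ("C1", "C", 9, "LIG", "L"),
        ]
        topo = _topo(atoms)
        frame = Frame(np.array([[d, 0, 0], [0.0, 0, 0]]))
        lig = AtomSelection("lig", (1,))
        return topo, frame, lig

    def test_close_carbon_pair_detected(self):
        topo, frame, lig = self._system(("CD1", "C"), 3.8)
        assert len(detect_hydrophobic(frame, topo, lig)) == 1

    def test_distant_pair_rejected(self):
        topo, frame, lig = self._system(("CD1", "C"), 4.5)
        assert detect_hydrophobic(frame, topo, lig) == []

    def test_polar_atom_excluded(self):
        topo, frame, lig = self._system(("OD1", "O"), 3.0)
        assert detect_hydrophobic(frame, topo, lig) == []

    def test_carbon_bonded_to_oxygen_is_polar(self):
        # ligand carbon with an oxygen 1.4 Å away is excluded
        atoms = [
            ("CD1", "C", 1, "LEU", "A"),
            ("C1", "C", 9, "LIG", "L"),
            ("O1", "O", 9, "LIG", "L"),
        ]
        topo = _topo(atoms)
        frame = Frame(np.array([[3.0, 0, 0], [0.0, 0, 0], [0.0, 1.4, 0]]))
        lig = AtomSelection("lig", (1, 2))
        assert detect_hydrophobic(frame, topo, lig) == []


class TestPiDetectors:
    def _rings(self, offset, tilt_deg=0.0):
        a = _hexagon(np.zeros(3))
        b = _hexagon(np.zeros(3))
        if tilt_deg:
            from scipy.spatial.transform import Rotation

            b = Rotation.from_euler("x", tilt_deg, degrees=True).apply(b)
        b = b + np.asarray(offset, dtype=float)
        atoms = [(f"C{i}", "C", 1, "PHE", "A") for i in range(6)] + [
            (f"C{i}L", "C", 9, "LIG", "L") for i in range(6)
        ]
        topo = _topo(atoms)
        frame = Frame(np.vstack([a, b]))
        return (
            topo,
            frame,
            AtomSelection("a", tuple(range(6))),
            AtomSelection("b", tuple(range(6, 12))),
        )

    def test_parallel_close_rings_stack(self):
        topo, frame, ra, rb = self._rings((0, 0, 3.8))
        events = detect_pi_stack(frame, topo, ra, rb)
        assert len(events) == 1
        assert events[0].distance == pytest.approx(3.8)

    def test_distant_rings_rejected(self):
        topo, frame, ra, rb = self._rings((0, 0, 6.0))
        assert detect_pi_stack(frame, topo, ra, rb) == []

    def test_perpendicular_rings_rejected(self):
        topo, frame, ra, rb = self._rings((0, 0, 3.8), tilt_deg=90.0)
        assert detect_pi_stack(frame, topo, ra, rb) == []

    def _ring_ion(self, ion_pos):
        ring = _hexagon(np.zeros(3))
        atoms = [(f"C{i}", "C", 9, "LIG", "L") for i in range(6)] + [
            ("OD1", "O", 1, "ASP", "A")
        ]
        topo = _topo(atoms)
        frame = Frame(np.vstack([ring, np.asarray(ion_pos, float)[None]]))
        return topo, frame, AtomSelection("r", tuple(range(6))), AtomSelection("i", (6,))

    def test_on_axis_ion_detected(self):
        topo, frame, ring, ion = self._ring_ion((0, 0, 3.5))
        events = detect_pi_ion(frame, topo, ring, ion)
        assert len(events) == 1 and events[0].distance == pytest.approx(3.5)

    def test_in_plane_ion_rejected(self):
        topo, frame, ring, ion = self._ring_ion((3.5, 0, 0))
        assert detect_pi_ion(frame, topo, ring, ion) == []

    def test_far_on_axis_ion_rejected(self):
        topo, frame, ring, ion = self._ring_ion((0, 0, 5.5))
        assert detect_pi_ion(frame, topo, ring, ion) == []


class TestEventSelfConsistency:
    @settings(max_examples=10, derandomize=True, deadline=None)
    @given(frame_pick=st.integers(0, 599))
    def test_every_event_resatisfies_its_criteria(self, planted_ensemble, frame_pick):
        ens, _ = planted_ensemble
        topo = ens.topology
        frame = ens.frames[frame_pick]
        cfg = ContactConfig()
        lig = resolve_selection(topo, "resname TYL")
        for ev in detect_hydrophobic(frame, topo, lig, cfg):
            d = np.linalg.norm(frame.coords[ev.atoms[0]] - frame.coords[ev.atoms[1]])
            assert d <= cfg.hydrophobic_dist
            assert d == pytest.approx(ev.distance)
        donors = AtomSelection(
            "polar",
            tuple(
                i
                for i, a in enumerate(topo.atoms)
                if a.element in ("N", "O") and a.residue_name != "TYL"
            ),
        )
        acceptors = resolve_selection(topo, "resname TYL and name O4")
        for ev in detect_hbonds(frame, topo, donors, acceptors, cfg):
            d = np.linalg.norm(frame.coords[ev.atoms[0]] - frame.coords[ev.atoms[1]])
            assert d <= cfg.hbond_dist


class TestFingerprint:
    def test_planted_frequencies_recovered_exactly(self, planted_ensemble):
        ens, truth = planted_ensemble
        lig = resolve_selection(ens.topology, "resname TYL")
        for basin, freq in ((0, 0.85), (1, 0.75)):
            fp = fingerprint(
                ens, lig, frame_indices=truth.basin_frames(basin), scope=f"basin-{basin}"
            )
            for rn, typ in (
                (3, "hbond"),
                (5, "hydrophobic"),
                (8, "hbond"),
                (9, "hydrophobic"),
                (12, "hbond"),
                (21, "hydrophobic"),
            ):
                n_basin = len(truth.basin_frames(basin))
                expected = round(freq * n_basin) / n_basin
                assert fp.frequency(("A", rn), typ) == pytest.approx(expected)

    def test_never_contacting_residue_zero(self, planted_ensemble):
        ens, truth = planted_ensemble
        lig = resolve_selection(ens.topology, "resname TYL")
        fp = fingerprint(ens, lig, frame_indices=truth.basin_frames(0))
        assert fp.frequency(("A", 20), "hbond") == 0.0
        assert fp.frequency(("A", 20), "hydrophobic") == 0.0

    def test_always_contacting_residue_one(self):
        spec = ps.synthetic.default_two_basin_spec(
            n_frames=40,
            occupancies=(0.5, 0.5),
            planted_contacts=[
                ps.synthetic.PlantedContact(("A", 7), "hbond", b, 1.0) for b in (0, 1)
            ],
            planted_prs=None,
            seed=6,
        )
        ens, _ = ps.synthetic.generate_two_basin_ensemble(spec)
        lig = resolve_selection(ens.topology, "resname TYL")
        fp = fingerprint(ens, lig)
        assert fp.frequency(("A", 7), "hbond") == 1.0

    def test_frequencies_bounded_and_permutation_invariant(self, planted_ensemble):
        ens, truth = planted_ensemble
        lig = resolve_selection(ens.topology, "resname TYL")
        frames = truth.basin_frames(1)
        fp1 = fingerprint(ens, lig, frame_indices=frames)
        fp2 = fingerprint(ens, lig, frame_indices=list(reversed(frames)))
        assert fp1.frequencies == fp2.frequencies
        assert all(0.0 <= f <= 1.0 for f in fp1.frequencies.values())


class TestHotspotSelection:
    def _fp(self, freqs, n=100, scope="b"):
        return InteractionFingerprint(frequencies=freqs, n_frames=n, scope=scope)

    def test_persistent_in_both_basins_selected(self):
        fps = {
            0: self._fp({(("A", 5), "hbond"): 0.8}),
            1: self._fp({(("A", 5), "hbond"): 0.7}),
        }
        got = select_hotspots(fps, 0.5, True)
        assert [rk for rk, _, _ in got] == [("A", 5)]

    def test_single_basin_persistence_excluded_when_all_required(self):
        fps = {
            0: self._fp({(("A", 5), "hbond"): 0.9}),
            1: self._fp({(("A", 5), "hbond"): 0.1}),
        }
        assert select_hotspots(fps, 0.5, True) == []
        assert len(select_hotspots(fps, 0.5, False)) == 1

    def test_planted_hotspot_set_recovered_exactly(self, planted_ensemble):
        ens, truth = planted_ensemble
        lig = resolve_selection(ens.topology, "resname TYL")
        fps = {
            b: fingerprint(ens, lig, frame_indices=truth.basin_frames(b))
            for b in (0, 1)
        }
        got = {rk for rk, _, _ in select_hotspots(fps, 0.5, True)}
        assert got == {("A", 3), ("A", 5), ("A", 8), ("A", 9), ("A", 12), ("A", 21)}

    def test_ranking_by_mean_frequency_then_resnum(self):
        fps = {
            0: self._fp(
                {
                    (("A", 9), "hbond"): 0.9,
                    (("A", 2), "hbond"): 0.7,
                    (("A", 4), "hbond"): 0.7,
                }
            )
        }
        got = [rk for rk, _, _ in select_hotspots(fps, 0.5, True)]
        assert got == [("A", 9), ("A", 2), ("A", 4)]
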