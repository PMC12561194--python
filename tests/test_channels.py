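"""Tunnel metrics, grid tunnel search, pocket estimation and CSV I/O."""

from __future__ import annotations

import numpy as np
import pytest

from pocketshaper.channels import (
    TunnelProfile,
    grid_tunnel_search,
    pocket_metrics,
    read_tunnel_profile_csv,
    tunnel_metrics,
    write_tunnel_profile_csv,
)
from pocketshaper.core import Atom, Frame, Topology
from pocketshaper.synthetic import ToyTunnelSpec, generate_toy_tunnel


def _profile(centers, radii):
    return TunnelProfile(
        spheres=tuple((tuple(map(float, c)), float(r)) for c, r in zip(centers, radii))
    )


def _atom_cloud(points, element="C"):
    topo = Topology(
        tuple(Atom("X", element, i + 1, "WAL", "A") for i in range(len(points)))
    )
    return topo, Frame(np.asarray(points, dtype=float))


def _cylinder_shell(radius, z_lo, z_hi, spacing=0.7):
    """Dense atom shell on a cylinder surface around the z axis."""
    pts = []
    n_phi = max(8, int(round(2 * np.pi * radius / spacing)))
    for z in np.arange(z_lo, z_hi + 1e-9, spacing):
        for k in range(n_phi):
            phi = 2 * np.pi * k / n_phi
            pts.append((radius * np.cos(phi), radius * np.sin(phi), z))
    return pts


def _sphere_shell(radius, spacing=0.7, center=(0, 0, 0), keep=lambda p: True):
    pts = []
    n = max(50, int(4 * np.pi * radius**2 / spacing**2))
    # Fibonacci sphere gives near-uniform coverage deterministically
    ga = np.pi * (3 - np.sqrt(5))
    for i in range(n):
        z = 1 - 2 * (i + 0.5) / n
        r = np.sqrt(1 - z * z)
        th = ga * i
        p = radius * np.array([r * np.cos(th), r * np.sin(th), z]) + center
        if keep(p):
            pts.append(tuple(p))
    return pts


class TestTunnelMetrics:
    def test_collinear_centerline_length_and_unit_curvature(self):
        m = tunnel_metrics(
            _profile([(0, 0, 0), (0, 0, 10), (0, 0, 20)], [2.0, 2.0, 2.0])
        )
        assert m.length == pytest.approx(20.0)
        assert m.curvature == pytest.approx(1.0)
        assert m.bottleneck_radius == 2.0

    def test_semicircle_curvature_approaches_pi_over_two(self):
        ang = np.radians(np.arange(0, 181, 1))
        centers = np.column_stack(
            [10 * np.cos(ang), 10 * np.sin(ang), np.zeros(ang.size)]
        )
        m = tunnel_metrics(_profile(centers, np.full(ang.size, 1.0)))
        assert m.curvature == pytest.approx(np.pi / 2, rel=1e-3)

    def test_cost_and_throughput_hand_evaluated(self):
        # uniform radius 2 Å over 10 Å: cost = 10/4 = 2.5, throughput e^-2.5
        centers = [(0, 0, z) for z in range(11)]
        m = tunnel_metrics(_profile(centers, [2.0] * 11), cost_scale=1.0)
        assert m.cost == pytest.approx(2.5)
        assert m.throughput == pytest.approx(np.exp(-2.5), rel=1e-12)

    def test_coincident_endpoints_rejected(self):
        ang = np.linspace(0, 2 * np.pi, 20)
        centers = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(20)])
        with pytest.raises(ValueError, match="curvature"):
            tunnel_metrics(_profile(centers, np.ones(20)))

    @pytest.mark.parametrize("lengths", [np.linspace(5, 25, 5)])
    def test_throughput_monotone_in_length_and_radius(self, lengths):
        radii = np.linspace(1.0, 3.0, 5)
        for r in radii:
            ts = []
            for L in lengths:
                n = int(L) + 1
                centers = [(0, 0, z * L / (n - 1)) for z in range(n)]
                ts.append(tunnel_metrics(_profile(centers, [r] * n)).throughput)
            assert all(a > b for a, b in zip(ts, ts[1:]))  # longer ⇒ lower
        for L in lengths:
            n = int(L) + 1
            centers = [(0, 0, z * L / (n - 1)) for z in range(n)]
            ts = [
                tunnel_metrics(_profile(centers, [r] * n)).throughput for r in radii
            ]
            assert all(a < b for a, b in zip(ts, ts[1:]))  # wider ⇒ higher

    def test_curvature_at_least_one(self, rng):
        for _ in range(20):
            centers = np.cumsum(rng.normal(0, 1, size=(6, 3)), axis=0)
            if np.linalg.norm(centers[-1] - centers[0]) < 1e-6:
                continue
            m = tunnel_metrics(_profile(centers, np.ones(6)))
            assert m.curvature >= 1.0 - 1e-9


class TestGridTunnelSearch:
    def _cavity_with_channel(self, channel_clearance=2.0):
        """Spherical cavity (clearance 3) with one cylindrical exit along +z
        of the requested clearance (atom radius C = 1.7).  The cylinder wall
        begins at the sphere surface so it does not intrude into the cavity."""
        r_atom = 1.7
        r_sph = 4.7 + r_atom
        r_wall = channel_clearance + r_atom
        z0 = np.sqrt(r_sph**2 - r_wall**2)
        pts = _sphere_shell(
            r_sph, spacing=0.6,
            keep=lambda p: not (p[2] > 0 and np.hypot(p[0], p[1]) < r_wall),
        )
        pts += _cylinder_shell(r_wall, z0, 12.0, spacing=0.6)
        return _atom_cloud(pts)

    def test_channel_found_with_bottleneck_near_construction(self):
        topo, frame = self._cavity_with_channel(2.0)
        prof = grid_tunnel_search(frame, topo, (0, 0, 0), 1.4, 0.5)
        assert prof is not None
        m = tunnel_metrics(prof)
        assert m.bottleneck_radius == pytest.approx(2.0, abs=0.5)
        assert prof.centers[-1][2] > 8.0  # exits through the +z channel

    def test_sealed_cavity_reports_no_tunnel(self):
        pts = _sphere_shell(6.0, spacing=0.55)
        topo, frame = _atom_cloud(pts)
        assert grid_tunnel_search(frame, topo, (0, 0, 0), 1.4, 0.6) is None

    def test_two_exits_takes_the_wider_channel(self):
        # narrow (1.5 Å) exit up, wide (3.0 Å) exit down; each cylinder
        # wall starts at the sphere surface so it does not intrude into
        # the cavity around the start point
        r_atom = 1.7
        r_sph = 4.7 + r_atom
        w_narrow, w_wide = 1.5 + r_atom, 3.0 + r_atom
        z_narrow = np.sqrt(r_sph**2 - w_narrow**2)
        z_wide = -np.sqrt(r_sph**2 - w_wide**2)
        keep = lambda p: not (
            (p[2] > 0 and np.hypot(p[0], p[1]) < w_narrow)
            or (p[2] < 0 and np.hypot(p[0], p[1]) < w_wide)
        )
        pts = _sphere_shell(r_sph, spacing=0.6, keep=keep)
        pts += _cylinder_shell(w_narrow, z_narrow, 14.0, spacing=0.6)
        pts += _cylinder_shell(w_wide, -14.0, z_wide, spacing=0.6)
        topo, frame = _atom_cloud(pts)
        prof = grid_tunnel_search(frame, topo, (0, 0, 0), 1.4, 0.5)
        assert prof is not None
        assert prof.centers[-1][2] < -8.0  # bottleneck-optimal exit is −z

    def test_buried_start_rejected(self):
        pts = _sphere_shell(3.0, spacing=0.5)
        topo, frame = _atom_cloud(pts)
        with pytest.raises(ValueError, match="probe"):
            grid_tunnel_search(frame, topo, (0, 0, 2.9), 1.4, 0.5)

    def test_bottleneck_equals_threshold_connectivity_oracle(self):
        """Max-min Dijkstra bottleneck must equal the largest clearance
        threshold at which the start still reaches the boundary (BFS)."""
        from pocketshaper.channels import _clearance_grid

        topo, frame = self._cavity_with_channel(2.0)
        spacing = 0.9  # coarse grid ≤ ~22³ voxels over this system
        prof = grid_tunnel_search(frame, topo, (0, 0, 0), 1.4, spacing)
        assert prof is not None
        got = min(r for _, r in prof.spheres)

        pts, clearance = _clearance_grid(frame, topo, spacing, 1.4 + 2 * spacing)
        shape = clearance.shape
        lo = pts[0, 0, 0]
        ijk = tuple(np.round((np.zeros(3) - lo) / spacing).astype(int))

        def reaches_boundary(threshold):
            ok = clearance >= threshold
            if not ok[ijk]:
                return False
            seen = np.zeros(shape, bool)
            stack = [ijk]
            seen[ijk] = True
            while stack:
                u = stack.pop()
                if any(c in (0, s - 1) for c, s in zip(u, shape)):
                    return True
                for d in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                    (0, -1, 0), (0, 0, 1), (0, 0, -1),
                ):
                    v = tuple(c + dc for c, dc in zip(u, d))
                    if all(0 <= c < s for c, s in zip(v, shape)) and not seen[v] and ok[v]:
                        seen[v] = True
                        stack.append(v)
            return False

        thresholds = np.unique(clearance[clearance > 1.4])
        best = max(t for t in thresholds if reaches_boundary(t))
        assert got == pytest.approx(best, abs=1e-9)


class TestPocketMetrics:
    def test_cube_cavity_volume(self):
        # hollow 10×10×10 Å cube: walls of atoms leaving free clearance 5 Å
        r_atom = 1.7
        probe = 1.4
        half = 5.0 + r_atom + probe  # wall centers so free space is ±5
        grid = np.arange(-half, half + 1e-9, 0.7)
        pts = [
            (x, y, z)
            for x in grid
            for y in grid
            for z in grid
            if max(abs(x), abs(y), abs(z)) > half - 0.35
        ]
        topo, frame = _atom_cloud(pts)
        pm = pocket_metrics(frame, topo, (0, 0, 0), 0.5, probe)
        # free region is the cube interior where clearance > probe
        side = 2 * (half - r_atom - probe)
        assert pm.volume == pytest.approx(side**3, rel=0.05)
        assert not pm.unbounded

    @pytest.mark.parametrize("spacing,tol", [(0.5, 0.10), (0.35, 0.06)])
    def test_sphere_cavity_volume_converges(self, spacing, tol):
        pts = _sphere_shell(5.0 + 1.7 + 1.4, spacing=0.6)
        topo, frame = _atom_cloud(pts)
        pm = pocket_metrics(frame, topo, (0, 0, 0), spacing, 1.4)
        true = 4.0 / 3.0 * np.pi * 5.0**3
        assert pm.volume == pytest.approx(true, rel=tol)

    def test_sphere_surface_area_with_staircase_correction(self):
        pts = _sphere_shell(5.0 + 1.7 + 1.4, spacing=0.6)
        topo, frame = _atom_cloud(pts)
        pm = pocket_metrics(frame, topo, (0, 0, 0), 0.5, 1.4)
        assert pm.surface_area == pytest.approx(4 * np.pi * 25.0, rel=0.15)

    def test_open_bowl_flagged_unbounded(self):
        # hemisphere bowl open upward: the flood fill escapes through the
        # convex-hull cap at the rim plane and the site is not enclosed
        pts = _sphere_shell(8.1, spacing=0.6, keep=lambda p: p[2] <= 0.5)
        topo, frame = _atom_cloud(pts)
        pm = pocket_metrics(frame, topo, (0, 0, -2.0), 0.5, 1.4)
        assert pm.unbounded

    def test_seed_inside_atom_rejected(self):
        topo, frame = _atom_cloud([(0.0, 0.0, 0.0), (10.0, 10.0, 10.0)])
        with pytest.raises(ValueError, match="inside an atom|probe-accessible"):
            pocket_metrics(frame, topo, (0.1, 0.0, 0.0), 0.5, 1.4)


class TestProfileCSV:
    def test_round_trip_identity(self, tmp_path):
        prof = generate_toy_tunnel(
            ToyTunnelSpec(("arc", 8.0, 1.0), (1.0, 2.5, 1.2), 0.5)
        )
        path = tmp_path / "prof.csv"
        write_tunnel_profile_csv(prof, path)
        back = read_tunnel_profile_csv(path)
        assert np.allclose(back.centers, prof.centers, atol=1e-6)
        assert np.allclose(back.radii, prof.radii, atol=1e-6)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,z,radius\n0,0,0,1.0\n0,0,oops,1.0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_tunnel_profile_csv(path)

    def test_header_only_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("x,y,z,radius\n")
        with pytest.raises(ValueError, match="empty profile"):
            read_tunnel_profile_csv(path)
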