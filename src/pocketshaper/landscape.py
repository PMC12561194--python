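"""Reaction-coordinate series and 2D free-energy landscapes.

Given a conformational ensemble, this module computes per-frame reaction
coordinates (RMSD to a reference, radius of gyration, or the first two
principal components of the superposed coordinates), bins a pair of them
into a 2D histogram, and converts occupancy to relative free energy

    ΔG_ij = −k_B·T · ln(P_ij / P_max),

zeroed at the most populated bin.  Empty bins are flagged unreachable and
never assigned a finite ΔG.  Strict local minima of the surface are the
basins: the lowest is the global minimum (the most stable binding
conformation), the rest are metastable states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import AtomSelection, ConformationEnsemble, Frame, kabsch_rmsd, radius_of_gyration

__all__ = [
    "KB_KCAL",
    "ReactionCoordinateSeries",
    "FreeEnergySurface",
    "Basin",
    "rmsd_series",
    "rg_series",
    "pca_coordinates",
    "compute_fel",
    "find_minima",
    "representative_frame",
]

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹
KB_KCAL = 0.0019872


@dataclass(frozen=True)
class ReactionCoordinateSeries:
    name: str
    values: np.ndarray
    reference_description: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FreeEnergySurface:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    delta_g: np.ndarray  # kcal/mol; +inf on unreachable (empty) bins
    occupied: np.ndarray
    temperature_K: float
    x_name: str = "x"
    y_name: str = "y"

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature_K

    def bin_center(self, i: int, j: int) -> tuple[float, float]:
        return (
            0.5 * (self.x_edges[i] + self.x_edges[i + 1]),
            0.5 * (self.y_edges[j] + self.y_edges[j + 1]),
        )

    def bin_of_frames(
        self, x: "ReactionCoordinateSeries", y: "ReactionCoordinateSeries"
    ) -> np.ndarray:
        """(T, 2) bin indices of each frame, right-closed last bin."""
        ix = np.clip(np.digitize(x.values, self.x_edges) - 1, 0, len(self.x_edges) - 2)
        iy = np.clip(np.digitize(y.values, self.y_edges) - 1, 0, len(self.y_edges) - 2)
        return np.column_stack([ix, iy])

    def to_tsv(self, path) -> None:
        """ΔG matrix as TSV with "NA" marking unreachable bins."""
        with open(path, "w") as fh:
            fh.write(f"# x={self.x_name} y={self.y_name} T={self.temperature_K} K\n")
            for i in range(self.delta_g.shape[0]):
                row = [
                    f"{self.delta_g[i, j]:.6f}" if self.occupied[i, j] else "NA"
                    for j in range(self.delta_g.shape[1])
                ]
                fh.write("\t".join(row) + "\n")


@dataclass(frozen=True)
class Basin:
    bin_index: tuple[int, int]
    delta_g: float
    kind: str  # "global" | "local"
    member_frames: tuple[int, ...]
    representative_frame: int | None = None


def rmsd_series(
    ensemble: ConformationEnsemble,
    selection: AtomSelection,
    reference: Frame,
) -> ReactionCoordinateSeries:
    """Per-frame minimal RMSD (Å) to a fixed reference frame."""
    if selection.is_empty:
        raise ValueError("selection is empty")
    vals = np.array(
        [kabsch_rmsd(reference, f, selection) for f in ensemble.frames]
    )
    return ReactionCoordinateSeries(
        name="rmsd",
        values=vals,
        reference_description=f"frame_index={reference.frame_index}",
    )


def rg_series(
    ensemble: ConformationEnsemble,
    selection: AtomSelection,
    masses: Sequence[float] | None = None,
) -> ReactionCoordinateSeries:
    """Per-frame radius of gyration (Å) of the selection."""
    vals = np.array(
        [radius_of_gyration(f, selection, masses) for f in ensemble.frames]
    )
    return ReactionCoordinateSeries(name="rg", values=vals)


def pca_coordinates(
    ensemble: ConformationEnsemble, selection: AtomSelection
) -> tuple[ReactionCoordinateSeries, ReactionCoordinateSeries, tuple[float, float]]:
    """Projections onto the top-2 principal components of the coordinate
    covariance, after superposing every frame onto the ensemble mean.

    The sign convention is deterministic: each component is flipped so its
    largest-magnitude loading is positive.  Explained variance fractions
    are returned regardless of covariance rank.
    """
    from scipy.spatial.transform import Rotation

    if ensemble.n_frames < 3:
        raise ValueError("PCA needs ≥ 3 frames")
    idx = list(selection.resolved_indices)
    if not idx:
        raise ValueError("selection is empty")
    X = ensemble.coordinates()[:, idx, :]  # (T, n, 3)
    # iterative mean-structure superposition (two passes suffice here)
    mean = X.mean(axis=0)
    for _ in range(2):
        aligned = np.empty_like(X)
        mc = mean - mean.mean(axis=0)
        for t in range(X.shape[0]):
            xc = X[t] - X[t].mean(axis=0)
            rot, _ = Rotation.align_vectors(mc, xc)
            aligned[t] = rot.apply(xc)
        mean = aligned.mean(axis=0)
    flat = aligned.reshape(aligned.shape[0], -1)
    flat = flat - flat.mean(axis=0)
    cov = flat.T @ flat / (flat.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    explained = (
        (float(evals[0] / total), float(evals[1] / total)) if total > 0 else (0.0, 0.0)
    )
    comps = []
    for k in range(2):
        v = evecs[:, k]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        comps.append(flat @ v)
    pc1 = ReactionCoordinateSeries(name="pc1", values=comps[0])
    pc2 = ReactionCoordinateSeries(name="pc2", values=comps[1])
    return pc1, pc2, explained


def compute_fel(
    x: ReactionCoordinateSeries,
    y: ReactionCoordinateSeries,
    bins: tuple[int, int] = (40, 40),
    temperature_K: float = 300.0,
    x_edges: np.ndarray | None = None,
    y_edges: np.ndarray | None = None,
) -> FreeEnergySurface:
    """Bin two coordinate series and convert occupancy to ΔG (kcal/mol).

    Bins span [min, max] per axis (the last bin is right-closed); explicit
    edges may be given instead.  A zero-variance axis cannot be binned
    automatically and raises with advice to pass explicit edges.
    """
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    bx, by = bins
    if bx < 2 or by < 2:
        raise ValueError("need ≥ 2 bins per axis")
    for series, edges in ((x, x_edges), (y, y_edges)):
        if edges is None and np.ptp(series.values) == 0.0:
            raise ValueError(
                f"axis {series.name!r} has zero variance; "
                "pass explicit bin edges"
            )
    xe = x_edges if x_edges is not None else np.linspace(
        x.values.min(), x.values.max(), bx + 1
    )
    ye = y_edges if y_edges is not None else np.linspace(
        y.values.min(), y.values.max(), by + 1
    )
    counts, xe, ye = np.histogram2d(x.values, y.values, bins=[xe, ye])
    counts = counts.astype(int)
    occupied = counts > 0
    kT = KB_KCAL * temperature_K
    delta_g = np.full(counts.shape, np.inf)
    cmax = counts.max()
    delta_g[occupied] = -kT * np.log(counts[occupied] / cmax)
    return FreeEnergySurface(
        x_edges=xe,
        y_edges=ye,
        counts=counts,
        delta_g=delta_g,
        occupied=occupied,
        temperature_K=temperature_K,
        x_name=x.name,
        y_name=y.name,
    )


def find_minima(
    surface: FreeEnergySurface,
    min_separation_bins: int = 1,
    x: ReactionCoordinateSeries | None = None,
    y: ReactionCoordinateSeries | None = None,
) -> list[Basin]:
    """Strict local minima of the surface, merged by Chebyshev proximity.

    An occupied bin is a candidate if its ΔG is strictly below every
    occupied 8-neighbor (unreachable neighbors are ignored).  Candidates
    closer than ``min_separation_bins`` (Chebyshev distance) are merged,
    keeping the lower ΔG; ties break by (i, j) lexicographic order.  The
    lowest surviving basin is "global", the rest "local", sorted ascending
    by ΔG.  When the coordinate series are supplied, member frames (frames
    falling in the basin bin) are attached.
    """
    dg = surface.delta_g
    occ = surface.occupied
    bx, by = dg.shape
    candidates: list[tuple[int, int]] = []
    for i in range(bx):
        for j in range(by):
            if not occ[i, j]:
                continue
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    ni, nj = i + di, j + dj
                    if 0 <= ni < bx and 0 <= nj < by and occ[ni, nj]:
                        if dg[ni, nj] <= dg[i, j]:
                            is_min = False
                            break
                if not is_min:
                    break
            if is_min:
                candidates.append((i, j))

    # merge close candidates, keeping the lower ΔG (ties: lexicographic)
    candidates.sort(key=lambda ij: (dg[ij], ij))
    kept: list[tuple[int, int]] = []
    for ij in candidates:
        if all(
            max(abs(ij[0] - k[0]), abs(ij[1] - k[1])) >= min_separation_bins
            for k in kept
        ):
            kept.append(ij)

    members: dict[tuple[int, int], list[int]] = {ij: [] for ij in kept}
    if x is not None and y is not None:
        frame_bins = surface.bin_of_frames(x, y)
        for t, (bi, bj) in enumerate(frame_bins):
            key = (int(bi), int(bj))
            if key in members:
                members[key].append(t)

    basins = []
    for rank, ij in enumerate(kept):
        basins.append(
            Basin(
                bin_index=ij,
                delta_g=float(dg[ij]),
                kind="global" if rank == 0 else "local",
                member_frames=tuple(members[ij]),
            )
        )
    return basins


def representative_frame(
    basin: Basin,
    surface: FreeEnergySurface,
    x: ReactionCoordinateSeries,
    y: ReactionCoordinateSeries,
) -> int:
    """Member frame closest to the basin bin center in standardized
    (z-scored) coordinate space; ties go to the lowest frame index."""
    if not basin.member_frames:
        raise ValueError("basin has no member frames")
    mx, sx = x.values.mean(), x.values.std()
    my, sy = y.values.mean(), y.values.std()
    sx = sx if sx > 0 else 1.0
    sy = sy if sy > 0 else 1.0
    cx, cy = surface.bin_center(*basin.bin_index)
    cz = np.array([(cx - mx) / sx, (cy - my) / sy])
    best_t, best_d = None, np.inf
    for t in basin.member_frames:
        p = np.array([(x.values[t] - mx) / sx, (y.values[t] - my) / sy])
        d = float(np.linalg.norm(p - cz))
        if d < best_d - 1e-15:
            best_d, best_t = d, t
    return int(best_t)
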