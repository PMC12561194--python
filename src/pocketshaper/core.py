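"""Ensemble data model, multi-model PDB I/O, atom selections and geometry.

A :class:`ConformationEnsemble` is a fixed :class:`Topology` (atom identities)
plus an ordered list of :class:`Frame` coordinate sets in Å — the in-memory
form of a conformational ensemble such as snapshots saved from a molecular
dynamics run.  Every downstream stage (reaction coordinates, free-energy
surfaces, interaction fingerprints, pre-reaction-state statistics) consumes
this object.

Coordinates are always Å; no unit autodetection is attempted.  Residues are
keyed by ``(chain_id, residue_number)``; the residue name is used only for
display and selection matching.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "ConformationEnsemble",
    "AtomSelection",
    "PDBFormatError",
    "SelectionSyntaxError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "resolve_selection",
    "kabsch_rmsd",
    "radius_of_gyration",
    "equilibration_window",
]


class PDBFormatError(ValueError):
    """Raised when a multi-model PDB file violates the format contract."""


class SelectionSyntaxError(ValueError):
    """Raised on a malformed selection expression; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Atom:
    atom_name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass(frozen=True)
class Topology:
    """Ordered atom identities shared by every frame of an ensemble."""

    atoms: tuple[Atom, ...]

    def __post_init__(self):
        if len(self.atoms) < 1:
            raise ValueError("Topology needs at least one atom")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_keys(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)


@dataclass(frozen=True)
class Frame:
    """One N×3 coordinate set (Å) of an ensemble."""

    coords: np.ndarray
    frame_index: int = 0
    time_ps: float | None = None

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must be an N×3 array")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords must be finite")
        if self.frame_index < 0:
            raise ValueError("frame_index must be ≥ 0")
        object.__setattr__(self, "coords", c)


@dataclass(frozen=True)
class ConformationEnsemble:
    """Immutable topology + ordered frames; frame indices strictly increase."""

    topology: Topology
    frames: tuple[Frame, ...]

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("ensemble needs at least one frame")
        n = self.topology.n_atoms
        last = -1
        for f in self.frames:
            if f.coords.shape[0] != n:
                raise ValueError(
                    f"frame {f.frame_index} has {f.coords.shape[0]} atoms, "
                    f"topology has {n}"
                )
            if f.frame_index <= last:
                raise ValueError("frame_index must be strictly increasing")
            last = f.frame_index
        object.__setattr__(self, "frames", tuple(self.frames))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """All coordinates stacked as a (T, N, 3) array."""
        return np.stack([f.coords for f in self.frames])


@dataclass(frozen=True)
class AtomSelection:
    """A resolved atom selection: the expression plus ascending indices."""

    expression: str
    resolved_indices: tuple[int, ...]

    def __post_init__(self):
        idx = tuple(int(i) for i in self.resolved_indices)
        if list(idx) != sorted(set(idx)):
            raise ValueError("resolved_indices must be unique and ascending")
        object.__setattr__(self, "resolved_indices", idx)

    @property
    def is_empty(self) -> bool:
        return len(self.resolved_indices) == 0

    def __len__(self) -> int:
        return len(self.resolved_indices)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def read_multimodel_pdb(path) -> ConformationEnsemble:
    """Read a multi-model PDB file into an ensemble.

    One :class:`Frame` per MODEL (or a single frame for a file without MODEL
    records), ``frame_index`` following model order from 0.  ATOM and HETATM
    records are both retained.  Raises :class:`PDBFormatError` when models
    disagree on atom count or a coordinate field fails to parse.
    """
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - biotite error paths
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc

    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise PDBFormatError(
            f"inconsistent or unparsable model records in {path}: {exc}"
        ) from exc

    if stack.array_length() == 0:
        raise PDBFormatError(f"no atoms in {path}")

    atoms = tuple(
        Atom(
            atom_name=str(stack.atom_name[i]),
            element=str(stack.element[i]),
            residue_number=int(stack.res_id[i]),
            residue_name=str(stack.res_name[i]),
            chain_id=str(stack.chain_id[i]),
        )
        for i in range(stack.array_length())
    )
    topo = Topology(atoms)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    frames = tuple(Frame(coords=c, frame_index=i) for i, c in enumerate(coords))
    return ConformationEnsemble(topology=topo, frames=frames)


def write_multimodel_pdb(ensemble: ConformationEnsemble, path) -> None:
    """Write an ensemble as a standard multi-model PDB (MODEL/ENDMDL).

    Coordinates use the fixed-width 8.3 PDB convention; magnitudes above
    9999.999 Å cannot be represented and raise a range error.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    allc = ensemble.coordinates()
    if np.any(np.abs(allc) > 9999.999):
        raise ValueError("coordinate magnitude exceeds the PDB 8.3 field range")

    n = ensemble.topology.n_atoms
    arr = struc.AtomArrayStack(ensemble.n_frames, n)
    topo = ensemble.topology
    arr.atom_name = np.array([a.atom_name for a in topo.atoms])
    arr.element = np.array([a.element for a in topo.atoms])
    arr.res_id = np.array([a.residue_number for a in topo.atoms])
    arr.res_name = np.array([a.residue_name for a in topo.atoms])
    arr.chain_id = np.array([a.chain_id for a in topo.atoms])
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = allc
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------
#
# Grammar (documented in docs/methods.md):
#   expr   := term ("or" term)*
#   term   := factor ("and" factor)*
#   factor := KEY VALUE | "(" expr ")"
#   KEY    := chain | resnum | resname | name
#
# "and" binds tighter than "or".  Values are matched case-sensitively;
# resnum values must be integers.

_TOKEN_RE = re.compile(r"\s*(\(|\)|\S+)")


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _SelParser:
    _KEYS = ("chain", "resnum", "resname", "name")

    def __init__(self, expression: str, topology: Topology):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.i = 0
        self.topology = topology

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, len(self.expression))

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty selection expression", 0)
        mask = self._expr()
        tok, pos = self._peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok!r}", pos)
        return mask

    def _expr(self) -> np.ndarray:
        mask = self._term()
        while self._peek()[0] == "or":
            self.i += 1
            mask = mask | self._term()
        return mask

    def _term(self) -> np.ndarray:
        mask = self._factor()
        while self._peek()[0] == "and":
            self.i += 1
            mask = mask & self._factor()
        return mask

    def _factor(self) -> np.ndarray:
        tok, pos = self._peek()
        if tok == "(":
            self.i += 1
            mask = self._expr()
            tok2, pos2 = self._peek()
            if tok2 != ")":
                raise SelectionSyntaxError("expected ')'", pos2)
            self.i += 1
            return mask
        if tok not in self._KEYS:
            raise SelectionSyntaxError(
                f"expected one of {self._KEYS} or '(', got {tok!r}", pos
            )
        self.i += 1
        val, vpos = self._peek()
        if val is None or val in ("and", "or", "(", ")"):
            raise SelectionSyntaxError(f"missing value after {tok!r}", vpos)
        self.i += 1
        atoms = self.topology.atoms
        if tok == "chain":
            return np.array([a.chain_id == val for a in atoms])
        if tok == "resname":
            return np.array([a.residue_name == val for a in atoms])
        if tok == "name":
            return np.array([a.atom_name == val for a in atoms])
        # resnum
        try:
            num = int(val)
        except ValueError:
            raise SelectionSyntaxError(f"resnum value {val!r} is not an integer", vpos)
        return np.array([a.residue_number == num for a in atoms])


def resolve_selection(topology: Topology, expression: str) -> AtomSelection:
    """Resolve a selection expression against a topology.

    An empty match is allowed (and queryable via ``AtomSelection.is_empty``);
    a syntax error raises :class:`SelectionSyntaxError` with the position.
    """
    mask = _SelParser(expression, topology).parse()
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    return AtomSelection(expression=expression, resolved_indices=indices)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def _selected(frame: Frame, selection: AtomSelection) -> np.ndarray:
    if selection.is_empty:
        raise ValueError(f"selection {selection.expression!r} is empty")
    return frame.coords[list(selection.resolved_indices)]


def kabsch_rmsd(ref: Frame, mobile: Frame, selection: AtomSelection) -> float:
    """Minimal RMSD (Å) of ``mobile`` onto ``ref`` over rigid motions.

    The optimal proper rotation (reflections excluded by construction) is
    obtained by the Kabsch procedure after centering both selections.  For
    fewer than 3 atoms or (near-)degenerate geometry a warning flags the
    ill-conditioned superposition; the value is still defined.
    """
    a = _selected(ref, selection)
    b = _selected(mobile, selection)
    if a.shape != b.shape:
        raise ValueError("selections differ in size between frames")
    n = a.shape[0]
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    if n < 3 or np.linalg.matrix_rank(ac, tol=1e-8) < 2:
        warnings.warn(
            "degenerate superposition (<3 atoms or collinear reference); "
            "RMSD is still defined but the rotation is not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        # align_vectors warns on its own for rank-deficient inputs
        warnings.simplefilter("ignore", UserWarning)
        _, rssd = Rotation.align_vectors(ac, bc)
    return float(rssd / np.sqrt(n))


def radius_of_gyration(
    frame: Frame,
    selection: AtomSelection,
    masses: Sequence[float] | None = None,
) -> float:
    """Mass-weighted radius of gyration (Å) of the selected atoms.

    ``sqrt(Σ mᵢ‖rᵢ − r_com‖² / Σ mᵢ)``; uniform masses when ``masses`` is None.
    """
    r = _selected(frame, selection)
    if masses is None:
        m = np.ones(r.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape[0] != r.shape[0]:
            raise ValueError("masses length must match selection size")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")
    com = (m[:, None] * r).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((r - com) ** 2).sum(axis=1)).sum() / m.sum()))


def equilibration_window(
    series: Sequence[float], window: int, tolerance: float
) -> int:
    """Smallest start index from which every sliding-window mean stays within
    ``tolerance`` of the final-window mean.

    Candidate starts leave at least one full window before the final one
    (``start ≤ len − 2·window``), so a series that only settles inside its
    final window does not count as equilibrated.  Returns ``len(series)``
    when no candidate qualifies ("not equilibrated"); the caller detects
    that case by comparing the return value with the series length.
    """
    s = np.asarray(series, dtype=float)
    if window < 2:
        raise ValueError("window must be ≥ 2")
    if s.size < 2 * window:
        raise ValueError("series must be at least twice the window length")
    means = np.convolve(s, np.ones(window) / window, mode="valid")
    target = means[-1]
    ok = np.abs(means - target) <= tolerance
    # smallest start with all subsequent window means within tolerance
    suffix_ok = np.flip(np.cumprod(np.flip(ok.astype(int)))).astype(bool)
    hits = np.flatnonzero(suffix_ok)
    max_start = s.size - 2 * window
    if hits.size and hits[0] <= max_start:
        return int(hits[0])
    return int(s.size)
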