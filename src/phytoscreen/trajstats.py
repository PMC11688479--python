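"""Molecular-dynamics trajectory analytics from first principles.

Operates on a simple in-memory :class:`Trajectory` (F frames x A atoms x 3
Cartesian coordinates in Å, with per-atom names, residue ids, masses and
van der Waals radii) read from multi-model PDB or plain XYZ frames.

Implemented statistics:

* Kabsch least-squares superposition (proper rotation, reflection
  corrected);
* per-frame RMSD against a reference frame, after per-frame fitting;
* per-atom RMSF about the time-mean structure, after alignment to an
  iterated average structure;
* mass-weighted radius of gyration;
* solvent-accessible surface area by the Shrake-Rupley rolling-probe
  point-sampling construction;
* the dynamic cross-correlation matrix (DCCM) of atomic displacements;
* principal component analysis of the 3A x 3A coordinate covariance;
* k-means frame clustering into representative structures.

Alignment reference for RMSF/DCCM/PCA is the trajectory-average
structure, iterated twice (align to frame-0 mean, recompute the mean,
realign); the fixed point of that iteration is insensitive to the
starting frame for well-behaved trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

#: Bondi-style van der Waals radii (Å) for common elements; fallback 1.7.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW = 1.70

#: Standard atomic masses (amu) for the same elements; fallback 12.011.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
}
DEFAULT_MASS = 12.011

DEFAULT_PROBE = 1.4  # Å, water-sized probe
DEFAULT_SASA_POINTS = 960


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates with per-atom metadata."""

    coords: np.ndarray  # (F, A, 3) float, Å
    atom_names: list[str] = field(default_factory=list)
    residue_ids: list[int] = field(default_factory=list)
    masses: np.ndarray | None = None  # (A,) amu
    radii: np.ndarray | None = None  # (A,) Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        a = self.coords.shape[1]
        if not self.atom_names:
            self.atom_names = ["C"] * a
        if not self.residue_ids:
            self.residue_ids = list(range(1, a + 1))
        if self.masses is None:
            self.masses = np.array(
                [ATOMIC_MASSES.get(_element(n), DEFAULT_MASS) for n in self.atom_names]
            )
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.radii is None:
            self.radii = np.array(
                [VDW_RADII.get(_element(n), DEFAULT_VDW) for n in self.atom_names]
            )
        else:
            self.radii = np.asarray(self.radii, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, selection: Sequence[int] | str | None) -> np.ndarray:
        """Resolve a selection to atom indices.

        ``None`` selects all atoms; a string selects atoms by name (e.g.
        ``"CA"`` for the C-alpha trace); otherwise a sequence of indices.
        """
        if selection is None:
            return np.arange(self.n_atoms)
        if isinstance(selection, str):
            idx = np.array(
                [i for i, n in enumerate(self.atom_names) if n == selection], dtype=int
            )
            if idx.size == 0:
                raise ValueError(f"selection {selection!r} matches no atom")
            return idx
        idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise ValueError("empty selection")
        return idx


@dataclass(frozen=True)
class SeriesSummary:
    """A per-frame series plus its relative-frequency histogram."""

    values: np.ndarray
    bin_edges: np.ndarray
    relative_frequencies: np.ndarray

    @classmethod
    def from_values(cls, values: np.ndarray, bins: int = 30) -> "SeriesSummary":
        values = np.asarray(values, dtype=float)
        counts, edges = np.histogram(values, bins=bins)
        total = counts.sum()
        freqs = counts / total if total else counts.astype(float)
        return cls(values, edges, freqs)


def _element(atom_name: str) -> str:
    """Element guess from an atom name: leading alpha characters, PDB style."""
    stripped = atom_name.strip().upper()
    if stripped[:2] in VDW_RADII:
        return stripped[:2]
    return stripped[:1]


# ---------------------------------------------------------------- superposition

def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of ``mobile`` onto ``reference`` over a selection.

    Returns ``(rotation, translation, transformed)`` where
    ``transformed = mobile @ rotation.T + translation`` minimizes the
    selection RMSD.  The rotation is proper (det = +1); a reflection in
    the raw SVD solution is corrected by flipping the smallest singular
    direction.  Raises when fewer than 3 non-collinear atoms are selected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    p = mobile[sel]
    q = reference[sel]
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(p0, tol=1e-10) < 2:
        raise ValueError("selected atoms are collinear; rotation is underdetermined")
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - rot @ pc
    transformed = mobile @ rot.T + trans
    return rot, trans, transformed


def _pair_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def aligned_coords(
    t: Trajectory, selection: Sequence[int] | str | None = None, iterations: int = 2
) -> np.ndarray:
    """All frames fitted (on the selection) to the iterated average structure."""
    sel = t.select(selection)
    coords = t.coords.copy()
    ref = coords[0]
    for _ in range(iterations):
        fitted = np.empty_like(coords)
        for f in range(t.n_frames):
            _, _, fitted[f] = kabsch_superpose(coords[f], ref, sel)
        ref = fitted.mean(axis=0)
        coords = fitted
    return coords


# ------------------------------------------------------------------ statistics

def rmsd_series(
    t: Trajectory,
    reference: np.ndarray | None = None,
    selection: Sequence[int] | str | None = None,
    bins: int = 30,
) -> SeriesSummary:
    """Per-frame mass-unweighted RMSD from a reference after per-frame fitting.

    The reference defaults to frame 0.  Fitting and RMSD use the same
    selection.
    """
    sel = t.select(selection)
    ref = t.coords[0] if reference is None else np.asarray(reference, dtype=float)
    values = np.empty(t.n_frames)
    for f in range(t.n_frames):
        _, _, fitted = kabsch_superpose(t.coords[f], ref, sel)
        values[f] = _pair_rmsd(fitted[sel], ref[sel])
    return SeriesSummary.from_values(values, bins=bins)


def rmsf(
    t: Trajectory,
    selection: Sequence[int] | str | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-atom RMSF about the time-mean position, in Å.

    With ``superpose=True`` (default) frames are first aligned to the
    iterated average structure; disable it for toys with a meaningful
    fixed lab frame.
    """
    sel = t.select(selection)
    coords = aligned_coords(t, sel) if superpose else t.coords
    sub = coords[:, sel, :]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(t: Trajectory, bins: int = 30) -> SeriesSummary:
    """Per-frame mass-weighted radius of gyration, in Å."""
    m = t.masses
    total = m.sum()
    values = np.empty(t.n_frames)
    for f in range(t.n_frames):
        r = t.coords[f]
        com = (m[:, None] * r).sum(axis=0) / total
        values[f] = math.sqrt(float((m * np.sum((r - com) ** 2, axis=1)).sum() / total))
    return SeriesSummary.from_values(values, bins=bins)


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points by the golden-spiral (Fibonacci) lattice."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    frame: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area of one frame, in Å².

    Each atom's sphere of radius r_i + probe is sampled with ``n_points``
    quasi-uniform points; a point is accessible iff it lies outside every
    other atom's inflated sphere.  Returns (total, per-atom) areas.
    """
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("van der Waals radii must be positive")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    a = frame.shape[0]
    inflated = radii + probe
    unit = _sphere_points(n_points)
    areas = np.empty(a)
    # Pairwise distances once; only neighbors with overlapping inflated
    # spheres can occlude sample points.
    diff = frame[:, None, :] - frame[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    for i in range(a):
        pts = frame[i] + inflated[i] * unit
        nbr = np.where((dist[i] < inflated[i] + inflated) & (np.arange(a) != i))[0]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbr:
            d2 = np.sum((pts - frame[j]) ** 2, axis=1)
            r2 = inflated[j] ** 2
            tol = 1e-6 * r2
            # Strictly interior points are occluded; points exactly ON a
            # shared surface (coincident/tangent spheres) are assigned to
            # the lowest-index atom so the union surface is counted once.
            blocked = d2 < r2 - tol
            if j < i:
                blocked |= np.abs(d2 - r2) <= tol
            accessible &= ~blocked
        areas[i] = accessible.mean() * 4.0 * math.pi * inflated[i] ** 2
    return float(areas.sum()), areas


def sasa_series(
    t: Trajectory,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SASA_POINTS,
    bins: int = 30,
) -> SeriesSummary:
    """Per-frame total SASA, in Å² (divide by 100 for nm²)."""
    values = np.array(
        [sasa(t.coords[f], t.radii, probe, n_points)[0] for f in range(t.n_frames)]
    )
    return SeriesSummary.from_values(values, bins=bins)


def dccm(
    t: Trajectory,
    selection: Sequence[int] | str | None = "CA",
    superpose: bool = True,
) -> np.ndarray:
    """Dynamic cross-correlation matrix of atomic displacements, in [-1, 1].

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>) with Δr the
    displacement from the time mean after alignment.  Symmetric, unit
    diagonal (atoms with zero variance get a diagonal 1 by convention).
    ``superpose=False`` skips alignment for toys with a meaningful lab
    frame (fitting redistributes planted motion across atoms).
    """
    sel = t.select(selection)
    coords = (aligned_coords(t, sel) if superpose else t.coords)[:, sel, :]
    delta = coords - coords.mean(axis=0)
    # cross[i, j] = mean over frames of dot(delta_i, delta_j)
    cross = np.einsum("fid,fjd->ij", delta, delta) / delta.shape[0]
    var = np.diag(cross).copy()
    norm = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(norm > 0, cross / norm, 0.0)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


@dataclass(frozen=True)
class PCAModes:
    eigenvalues: np.ndarray  # sorted descending, length 3A
    variance_fractions: np.ndarray
    projections: np.ndarray  # (F, 2): per-frame scores on the first two modes


def pca_modes(
    t: Trajectory,
    selection: Sequence[int] | str | None = None,
    superpose: bool = True,
) -> PCAModes:
    """PCA of the 3A x 3A covariance of aligned coordinates.

    Eigenvalues are sorted descending; ``variance_fractions`` sum to 1;
    ``projections`` are the per-frame scores on the first two modes.
    ``superpose=False`` skips alignment (see :func:`dccm`).
    """
    sel = t.select(selection)
    coords = (aligned_coords(t, sel) if superpose else t.coords)[:, sel, :]
    flat = coords.reshape(t.n_frames, -1)
    centered = flat - flat.mean(axis=0)
    cov = centered.T @ centered / centered.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    projections = centered @ evecs[:, :2]
    return PCAModes(evals, fractions, projections)


def cluster_frames(
    t: Trajectory,
    k: int = 10,
    seed: int = 0,
    selection: Sequence[int] | str | None = None,
) -> list[int]:
    """k-means clustering of aligned frames; returns one representative per cluster.

    Representatives are the frames nearest each centroid, listed in
    ascending frame order.  ``k >= n_frames`` returns every frame.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= t.n_frames:
        return list(range(t.n_frames))
    sel = t.select(selection)
    flat = aligned_coords(t, sel)[:, sel, :].reshape(t.n_frames, -1)
    km = KMeans(n_clusters=k, random_state=seed, n_init=50, max_iter=300)
    labels = km.fit_predict(flat)
    reps = []
    for c in range(k):
        members = np.where(labels == c)[0]
        d = np.linalg.norm(flat[members] - km.cluster_centers_[c], axis=1)
        reps.append(int(members[np.argmin(d)]))
    return sorted(reps)


# ----------------------------------------------------------------------- I/O

def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL records) as a trajectory."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    names = [str(n) for n in stack.atom_name]
    res_ids = [int(r) for r in stack.res_id]
    return Trajectory(coords=coords, atom_names=names, residue_ids=res_ids)


def write_multimodel_pdb(t: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arrays = []
    for f in range(t.n_frames):
        arr = struc.AtomArray(t.n_atoms)
        arr.coord = t.coords[f].astype(np.float32)
        arr.atom_name = np.array(t.atom_names)
        arr.res_id = np.array(t.residue_ids)
        arr.res_name = np.array(["GLY"] * t.n_atoms)
        arr.chain_id = np.array(["A"] * t.n_atoms)
        arr.element = np.array([_element(n) for n in t.atom_names])
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_xyz_frames(path: str | Path) -> Trajectory:
    """Read concatenated plain XYZ frames.

    Format per frame: an atom-count line, a comment line, then one
    ``name x y z`` line per atom.  All frames must share atom count and
    ordering.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    frames: list[np.ndarray] = []
    names: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"truncated XYZ frame at line {i + 1}")
        coords = np.empty((n, 3))
        frame_names = []
        for j, ln in enumerate(block):
            parts = ln.split()
            frame_names.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        if not names:
            names = frame_names
        elif frame_names != names:
            raise ValueError("XYZ frames disagree on atom names/order")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return Trajectory(coords=np.stack(frames), atom_names=names)


def write_xyz_frames(t: Trajectory, path: str | Path, comment: str = "") -> None:
    out = []
    for f in range(t.n_frames):
        out.append(str(t.n_atoms))
        out.append(f"frame {f} {comment}".rstrip())
        for name, (x, y, z) in zip(t.atom_names, t.coords[f]):
            out.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")
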