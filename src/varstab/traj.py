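"""Trajectory statistics: superposition RMSD, per-residue RMSF, radius of
gyration, equilibrium-window summaries, and group comparison.

Frames hold Cartesian coordinates in angstroms with per-atom masses.  The
root-mean-square deviation (RMSD) of a frame is the minimal weighted RMSD
against a reference after optimal rigid-body superposition (Kabsch
algorithm, reflections excluded).  The per-residue root-mean-square
fluctuation (RMSF) measures each atom's spread around its time-averaged
position after superposing every frame onto the (iterated) mean structure.
The radius of gyration Rg = sqrt(sum m_i |r_i - r_com|^2 / sum m_i) tracks
overall compactness.

Statistics over the post-equilibration window are summarised as mean +/- SD
and compared between systems with a normality-gated two-sample test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    GeometryError,
    InputError,
    InsufficientDataError,
    MassError,
    SelectionError,
    TrajectoryIntegrityError,
)

#: Atom-name presets for selections.
BACKBONE_NAMES = ("N", "CA", "C", "O")
CALPHA_NAMES = ("CA",)

_ELEMENT_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


@dataclass
class StructureFrame:
    """One snapshot: per-atom identity, masses (amu) and coordinates (A)."""

    atom_names: tuple[str, ...]
    residue_ids: np.ndarray  # 1-based residue index per atom
    elements: tuple[str, ...]
    masses: np.ndarray
    coords: np.ndarray  # (n_atoms, 3)
    time_ps: float = 0.0
    residue_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (len(self.elements) == self.residue_ids.size == self.masses.size == n):
            raise InputError("inconsistent per-atom array lengths")
        if self.coords.shape != (n, 3):
            raise InputError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if np.any(self.masses <= 0):
            raise MassError("non-positive atom mass")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def identity(self) -> tuple[tuple[int, str], ...]:
        return tuple(zip(self.residue_ids.tolist(), self.atom_names))


class Trajectory:
    """An ordered, identity-consistent sequence of frames."""

    def __init__(self, frames: Sequence[StructureFrame], spacing_tol: float = 1e-6):
        if not frames:
            raise InputError("empty trajectory")
        ident = frames[0].identity()
        for k, frame in enumerate(frames[1:], start=1):
            other = frame.identity()
            if other != ident:
                culprit = next(
                    (a for a, b in zip(ident, other) if a != b),
                    ident[min(len(other), len(ident) - 1)],
                )
                raise TrajectoryIntegrityError(
                    f"frame {k} atom set differs from frame 0 near residue "
                    f"{culprit[0]} atom {culprit[1]!r}"
                )
        times = np.array([f.time_ps for f in frames])
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise InputError("frame times must be strictly increasing")
            if np.ptp(dt) > spacing_tol * max(1.0, dt.mean()):
                raise InputError("non-uniform frame spacing")
        self.frames = list(frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])

    @property
    def times_ns(self) -> np.ndarray:
        return self.times_ps / 1000.0

    def coords_array(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_frames, n_selected, 3) coordinate stack."""
        if mask is None:
            return np.stack([f.coords for f in self.frames])
        return np.stack([f.coords[mask] for f in self.frames])


SelectionLike = str | Callable[[str, int], bool]


def selection_mask(frame: StructureFrame, selection: SelectionLike = "all") -> np.ndarray:
    """Boolean per-atom mask for a preset name or (name, resid) predicate."""
    if callable(selection):
        mask = np.array(
            [selection(n, int(r)) for n, r in zip(frame.atom_names, frame.residue_ids)]
        )
    else:
        preset = selection.lower()
        if preset == "all":
            mask = np.ones(frame.n_atoms, dtype=bool)
        elif preset == "backbone":
            mask = np.isin(frame.atom_names, BACKBONE_NAMES)
        elif preset == "calpha":
            mask = np.isin(frame.atom_names, CALPHA_NAMES)
        else:
            raise SelectionError(f"unknown selection preset {selection!r}")
    if not mask.any():
        raise SelectionError(f"selection {selection!r} matches no atoms")
    return mask


# ---------------------------------------------------------------------------
# multi-model PDB I/O


def read_multimodel_pdb(path: str | Path, dt_ps: float = 25.0) -> Trajectory:
    """Read a MODEL/ENDMDL multi-model PDB file as a trajectory.

    Frame times are assigned as model_index * dt_ps (PDB files carry no
    time axis).  Atom identity must be consistent across models.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("traj", str(path))
    frames: list[StructureFrame] = []
    for i, model in enumerate(structure):
        names, resids, resnames, elements, masses, coords = [], [], [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    names.append(atom.get_name())
                    resids.append(residue.id[1])
                    resnames.append(residue.get_resname())
                    element = (atom.element or "C").strip().upper()
                    elements.append(element)
                    mass = atom.mass
                    if mass is None or not np.isfinite(mass):
                        mass = _ELEMENT_MASS.get(element, 12.011)
                    masses.append(mass)
                    coords.append(atom.coord)
        if not names:
            raise InputError(f"{path}: model {i} has no ATOM records")
        frames.append(
            StructureFrame(
                atom_names=tuple(names),
                residue_ids=np.array(resids),
                elements=tuple(elements),
                masses=np.array(masses),
                coords=np.array(coords),
                time_ps=i * dt_ps,
                residue_names=tuple(resnames),
            )
        )
    if not frames:
        raise InputError(f"{path}: no models found")
    return Trajectory(frames)


def write_multimodel_pdb(traj: Trajectory | Sequence[StructureFrame], path: str | Path) -> None:
    """Write frames as fixed-column ATOM records in MODEL/ENDMDL blocks.

    Occupancy and B-factor are written as 1.00 and 0.00.
    """
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    lines: list[str] = []
    for m, frame in enumerate(frames, start=1):
        lines.append(f"MODEL     {m:>4}")
        resnames = frame.residue_names or ("GLY",) * frame.n_atoms
        for serial, (name, resid, resname, element, xyz) in enumerate(
            zip(frame.atom_names, frame.residue_ids, resnames, frame.elements, frame.coords),
            start=1,
        ):
            pdb_name = name if len(name) == 4 else f" {name:<3}"
            lines.append(
                f"ATOM  {serial:>5} {pdb_name} {resname:>3} A{int(resid):>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# superposition and derived statistics


@dataclass
class SuperpositionResult:
    """Optimal rigid transform: apply as coords @ rotation.T + translation."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted least-squares rigid superposition (reflections excluded).

    Returns the proper rotation and translation minimising the weighted
    RMSD of ``mobile`` onto ``reference`` and the minimal RMSD itself.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError(
            f"coordinate shapes differ or are not (n, 3): "
            f"{mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError(f"need >= 3 atoms for superposition, got {n}")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
        raise GeometryError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    x = mobile - mc
    y = reference - rc
    if min(np.linalg.matrix_rank(x, tol=1e-9), np.linalg.matrix_rank(y, tol=1e-9)) < 2:
        raise GeometryError("degenerate (collinear) coordinates")
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = x @ rot.T - y
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum()))
    translation = rc - rot @ mc
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def rmsd_series(
    traj: Trajectory,
    selection: SelectionLike = "backbone",
    reference: int | StructureFrame = 0,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame minimal RMSD (A) of the selected atoms vs the reference."""
    mask = selection_mask(traj.frames[0], selection)
    if isinstance(reference, StructureFrame):
        ref_coords = reference.coords[selection_mask(reference, selection)]
    else:
        ref_coords = traj.frames[reference].coords[mask]
    w = None if weights is None else np.asarray(weights, dtype=float)
    return np.array(
        [kabsch_superpose(f.coords[mask], ref_coords, w).rmsd for f in traj.frames]
    )


@dataclass
class RMSFProfile:
    """Per-residue RMSF (A) over the equilibrated window."""

    residues: np.ndarray
    values: np.ndarray


def rmsf_profile(
    traj: Trajectory,
    selection: SelectionLike = "calpha",
    equil_start_ns: float = 12.0,
    reference: str = "mean",
    tol: float = 1e-6,
    max_iter: int = 20,
) -> RMSFProfile:
    """Per-atom RMSF about the time-averaged structure.

    Frames at or after ``equil_start_ns`` are superposed onto the mean
    structure (iterated to convergence when ``reference='mean'``, or onto
    the first usable frame when ``reference='first'``); RMSF_i is the root
    mean squared displacement of atom i from its mean position.
    """
    mask = selection_mask(traj.frames[0], selection)
    usable = [f for f in traj.frames if f.time_ps >= equil_start_ns * 1000.0]
    if len(usable) < 2:
        raise InsufficientDataError(
            f"only {len(usable)} frames at/after {equil_start_ns} ns"
        )
    stack = np.stack([f.coords[mask] for f in usable])
    if reference == "first":
        ref = stack[0]
        aligned = _superpose_stack(stack, ref)
    elif reference == "mean":
        ref = stack[0]
        for _ in range(max_iter):
            aligned = _superpose_stack(stack, ref)
            new_ref = aligned.mean(axis=0)
            shift = float(np.sqrt(((new_ref - ref) ** 2).sum(axis=1).mean()))
            ref = new_ref
            if shift < tol:
                break
    else:
        raise InputError(f"unknown RMSF reference {reference!r}")
    mean_pos = aligned.mean(axis=0)
    disp2 = ((aligned - mean_pos) ** 2).sum(axis=2)
    values = np.sqrt(disp2.mean(axis=0))
    residues = traj.frames[0].residue_ids[mask]
    return RMSFProfile(residues=residues, values=values)


def _superpose_stack(stack: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return np.stack([kabsch_superpose(frame, ref).apply(frame) for frame in stack])


def radius_of_gyration(frame: StructureFrame) -> float:
    """Mass-weighted RMS distance of atoms from their centre of mass (A)."""
    total = frame.masses.sum()
    if total <= 0:
        raise MassError("zero total mass")
    com = (frame.masses[:, None] * frame.coords).sum(axis=0) / total
    d2 = ((frame.coords - com) ** 2).sum(axis=1)
    return float(np.sqrt((frame.masses * d2).sum() / total))


def rg_series(traj: Trajectory) -> np.ndarray:
    """Per-frame radius of gyration (A)."""
    return np.array([radius_of_gyration(f) for f in traj.frames])


@dataclass
class SeriesStats:
    """Mean +/- SD of a per-frame series over the equilibrated window."""

    mean: float
    sd: float
    window_start_ns: float
    n_frames: int


def equilibrium_stats(
    times_ns: np.ndarray, values: np.ndarray, equil_start_ns: float
) -> SeriesStats:
    """Mean and sample SD of the series at/after the equilibration time."""
    times_ns = np.asarray(times_ns, dtype=float)
    values = np.asarray(values, dtype=float)
    if times_ns.shape != values.shape:
        raise InputError("times and values must have matching shapes")
    window = values[times_ns >= equil_start_ns]
    if window.size < 2:
        raise InsufficientDataError(
            f"only {window.size} frames at/after {equil_start_ns} ns"
        )
    return SeriesStats(
        mean=float(window.mean()),
        sd=float(window.std(ddof=1)),
        window_start_ns=equil_start_ns,
        n_frames=int(window.size),
    )


@dataclass
class GroupComparison:
    """Two-sample comparison with a normality-gated test choice."""

    test_name: str
    statistic: float
    pvalue: float
    significant: bool
    alpha: float


def compare_groups(
    a: Iterable[float], b: Iterable[float], alpha: float = 0.05
) -> GroupComparison:
    """Student's t-test when both samples pass a Shapiro normality check
    (at 0.05), otherwise the Mann-Whitney U rank test; significant iff
    p < alpha."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("each sample needs >= 3 observations")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        # identical constant samples: no evidence of a difference
        return GroupComparison("t-test", 0.0, 1.0, False, alpha)
    normal = all(
        stats.shapiro(sample).pvalue >= 0.05 if np.ptp(sample) > 0 else False
        for sample in (a, b)
    )
    if normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        name = "t-test"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    p = float(res.pvalue)
    return GroupComparison(name, float(res.statistic), p, p < alpha, alpha)


#: Weights of the combined model-quality Z-score.
ZSCORE_WEIGHTS = {"dihedrals": 0.1456, "packing1d": 0.3906, "packing3d": 0.4656}


def model_zscore(dihedrals: float, packing1d: float, packing3d: float) -> float:
    """Combined homology-model quality Z-score.

    Weighted average of the dihedral, 1D-packing and 3D-packing Z-scores:
    0.1456 * dihedrals + 0.3906 * packing1d + 0.4656 * packing3d.
    """
    for v in (dihedrals, packing1d, packing3d):
        if not np.isfinite(v):
            raise InputError(f"non-finite Z-score component {v!r}")
    return (
        ZSCORE_WEIGHTS["dihedrals"] * dihedrals
        + ZSCORE_WEIGHTS["packing1d"] * packing1d
        + ZSCORE_WEIGHTS["packing3d"] * packing3d
    )
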