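"""Superposition, RMSD, average structures, and center-of-mass distances."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import MolecularSystem, NucleosomeAnnotation, TrajectorySegment, select_sites

__all__ = [
    "Superposition",
    "DistanceSeries",
    "kabsch_superpose",
    "fit_trajectory",
    "average_structure",
    "converged_average",
    "center_of_mass",
    "com_distance_series",
    "rmsd",
]


class GeometryError(ValueError):
    pass


@dataclass
class Superposition:
    """A proper rigid-body transform ``x -> x @ rotation.T + translation``."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class DistanceSeries:
    """A per-frame distance with its window summary statistics."""

    label: str
    values: np.ndarray  # Angstrom per frame
    times: np.ndarray   # ns

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values))

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    def summary(self) -> dict:
        return {"label": self.label, "mean": self.mean, "sd": self.sd,
                "min": self.min, "n_frames": int(len(self.values))}

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("frame\ttime_ns\tdistance_A\n")
            for i, (t, v) in enumerate(zip(self.times, self.values)):
                fh.write(f"{i}\t{t:.6g}\t{v:.6f}\n")


def rmsd(a: np.ndarray, b: np.ndarray,
         weights: np.ndarray | None = None) -> float:
    """Weighted root-mean-square deviation between matched coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    d2 = np.sum((a - b) ** 2, axis=1)
    if weights is None:
        return float(np.sqrt(np.mean(d2)))
    w = np.asarray(weights, float)
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation (reflections are never chosen) and translation
    minimising the weighted RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError(
            f"shape mismatch: mobile {mobile.shape}, reference {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    x = mobile - cm
    y = reference - cr
    h = (x * w[:, None]).T @ y  # 3x3 weighted covariance
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise GeometryError("degenerate (collinear) geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = x @ rot.T
    val = float(np.sqrt(max(np.sum(w * np.sum((moved - y) ** 2, axis=1)), 0.0)))
    translation = cr - cm @ rot.T
    return Superposition(rotation=rot, translation=translation, rmsd=val)


def fit_trajectory(traj: TrajectorySegment, selection_indices: np.ndarray,
                   reference: np.ndarray,
                   weights: np.ndarray | None = None) -> TrajectorySegment:
    """Superpose every frame onto ``reference`` using the selection atoms.

    The transform fitted on the selection is applied to all atoms.
    ``reference`` must cover the selection: either full-system coordinates or
    exactly the selection's atoms.
    """
    sel = np.asarray(selection_indices, dtype=int)
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] == traj.n_atoms:
        ref_sel = reference[sel]
    elif reference.shape[0] == sel.size:
        ref_sel = reference
    else:
        raise GeometryError(
            f"reference covers {reference.shape[0]} atoms; need the full system "
            f"({traj.n_atoms}) or the selection ({sel.size})")
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        try:
            sup = kabsch_superpose(traj.coords[f, sel], ref_sel, weights)
        except GeometryError as exc:
            raise GeometryError(f"frame {f}: {exc}") from exc
        out[f] = sup.apply(traj.coords[f])
    return replace(traj, coords=out, aligned=True)


def average_structure(traj: TrajectorySegment,
                      selection_indices: np.ndarray | None = None) -> np.ndarray:
    """Unweighted per-atom mean over the window frames (geometric average).

    Meaningful only on an aligned trajectory; alignment is the caller's
    responsibility.
    """
    if traj.n_window_frames == 0:
        raise GeometryError("empty analysis window")
    coords = traj.window_coords()
    if selection_indices is not None:
        coords = coords[:, np.asarray(selection_indices, dtype=int)]
    return coords.mean(axis=0)


def converged_average(traj: TrajectorySegment, selection_indices: np.ndarray,
                      n_iter: int = 2) -> tuple[TrajectorySegment, np.ndarray]:
    """Iteratively align to the running average (align -> average -> re-align).

    Returns the aligned trajectory and the final full-system average
    coordinates. Used as the default alignment reference when no
    energy-minimised structure is supplied.
    """
    sel = np.asarray(selection_indices, dtype=int)
    ref = traj.window_coords()[0]
    aligned = traj
    for _ in range(max(1, n_iter)):
        aligned = fit_trajectory(aligned, sel, ref)
        ref = average_structure(aligned)
    return aligned, ref


def center_of_mass(coords: np.ndarray, masses: np.ndarray,
                   group: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of a group of atoms."""
    g = np.asarray(group, dtype=int)
    if g.size == 0:
        raise GeometryError("empty group")
    m = np.asarray(masses, dtype=float)[g]
    total = m.sum()
    if total <= 0:
        raise GeometryError("zero total mass")
    return (m[:, None] * np.asarray(coords)[g]).sum(axis=0) / total


def com_distance_series(traj: TrajectorySegment, system: MolecularSystem,
                        group_a: np.ndarray, group_b: np.ndarray,
                        label: str = "COM distance") -> DistanceSeries:
    """Per-frame distance between the mass-weighted COMs of two disjoint groups."""
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if np.intersect1d(ga, gb).size:
        raise GeometryError("groups overlap; COM distance requires disjoint groups")
    coords = traj.window_coords()
    ma = system.masses[ga]
    mb = system.masses[gb]
    ca = (coords[:, ga] * ma[None, :, None]).sum(axis=1) / ma.sum()
    cb = (coords[:, gb] * mb[None, :, None]).sum(axis=1) / mb.sum()
    values = np.linalg.norm(ca - cb, axis=1)
    return DistanceSeries(label=label, values=values, times=traj.window_times())


def dimer_atoms(system: MolecularSystem, annotation: NucleosomeAnnotation,
                dimer: str, atom_class: str = "all") -> np.ndarray:
    """All atoms of the two chains forming a named dimer."""
    r1, r2 = annotation.dimers[dimer]
    parts = []
    for role in (r1, r2):
        sel = select_sites(system, annotation, role=role,
                           atom_class=atom_class, pooled=True)
        parts.append(sel.groups[0])
    return np.unique(np.concatenate(parts))
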