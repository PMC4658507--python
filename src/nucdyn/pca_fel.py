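"""C-alpha PCA, projections, representative structures, mode animations, and
2D free-energy landscapes with basin/barrier quantification.

The covariance of the 3N coordinate vector (N selection sites) about its mean
is diagonalised; eigenvalues are variances in A^2, eigenvectors orthonormal
3N-vectors in descending eigenvalue order. Landscapes are -kT ln of the
binned density of 2D projections, shifted so the minimum over occupied bins
is zero. Basins are found by flooding the occupied-bin graph (8-connectivity)
in order of increasing F; the level at which two catchments first connect is
the bottleneck (minimax) barrier level between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MolecularSystem, SiteSelection, TrajectorySegment, write_pdb

__all__ = [
    "PCAModel", "FreeEnergyLandscape", "BasinSet",
    "fit_pca", "project_frames", "representative_frame", "mode_animation",
    "free_energy_landscape", "find_basins",
]


class PCAError(ValueError):
    pass


@dataclass
class PCAModel:
    site_labels: list[str]
    atom_indices: np.ndarray     # selection atoms, sorted
    mean_coords: np.ndarray      # (3N,)
    eigenvectors: np.ndarray     # (k, 3N), orthonormal rows, descending
    eigenvalues: np.ndarray      # (k,) variances in A^2, non-increasing
    n_frames: int
    total_variance: float        # trace of the covariance

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    def to_json_dict(self) -> dict:
        return {
            "site_labels": self.site_labels,
            "eigenvalues": self.eigenvalues.tolist(),
            "n_frames": self.n_frames,
            "total_variance": self.total_variance,
        }


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|component| entry positive."""
    out = vectors.copy()
    for i, v in enumerate(out):
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[i] = -v
    return out


def fit_pca(traj: TrajectorySegment, selection: SiteSelection,
            require_aligned: bool = False) -> PCAModel:
    """PCA of the selection's Cartesian coordinates over the window.

    Uses a full symmetric eigendecomposition when 3N is small, otherwise an
    economy SVD of the centred frame matrix (equivalent spectra). Sample
    covariance uses the n-1 normalisation.
    """
    if require_aligned and not traj.aligned:
        raise PCAError("trajectory is not aligned (fit_trajectory first)")
    import warnings
    if not traj.aligned:
        warnings.warn("PCA on an unaligned trajectory; rigid-body motion will "
                      "leak into the modes", stacklevel=2)
    if traj.n_window_frames < 2:
        raise PCAError("PCA requires at least 2 frames")
    atoms = np.unique(np.concatenate(selection.groups))
    x = traj.window_coords()[:, atoms].reshape(traj.n_window_frames, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    f, d = xc.shape
    total_var = float(np.sum(xc ** 2) / (f - 1))
    if d <= max(f, 512):
        cov = xc.T @ xc / (f - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        eigvals = np.clip(w[order], 0.0, None)
        eigvecs = v[:, order].T
    else:
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        eigvals = s ** 2 / (f - 1)
        eigvecs = vt
    eigvecs = _fix_signs(eigvecs)
    return PCAModel(site_labels=list(selection.site_labels),
                    atom_indices=atoms, mean_coords=mean,
                    eigenvectors=eigvecs, eigenvalues=eigvals,
                    n_frames=f, total_variance=total_var)


def project_frames(traj: TrajectorySegment, model: PCAModel,
                   k: int = 2) -> np.ndarray:
    """Project window frames onto the top-k principal components (A units)."""
    if k > model.eigenvectors.shape[0]:
        raise PCAError(f"requested {k} components, model holds "
                       f"{model.eigenvectors.shape[0]}")
    x = traj.window_coords()[:, model.atom_indices].reshape(
        traj.n_window_frames, -1)
    if x.shape[1] != model.mean_coords.shape[0]:
        raise PCAError("selection does not match the PCA model")
    return (x - model.mean_coords) @ model.eigenvectors[:k].T


def representative_frame(traj: TrajectorySegment,
                         selection_indices: np.ndarray,
                         reference: np.ndarray | None = None) -> int:
    """Window frame with the lowest selection RMSD to the window average.

    Returns a global frame index; ties break to the earliest frame.
    """
    sel = np.asarray(selection_indices, dtype=int)
    coords = traj.window_coords()[:, sel]
    if reference is None:
        ref = coords.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape[0] == traj.n_atoms:
            ref = ref[sel]
    d = np.sqrt(np.mean(np.sum((coords - ref[None]) ** 2, axis=2), axis=1))
    return int(traj.window[0] + np.argmin(d))


def mode_animation(model: PCAModel, component: int,
                   base_coords: np.ndarray,
                   scalars: np.ndarray | None = None) -> np.ndarray:
    """Coordinate sets ``base + s * sqrt(eigenvalue) * eigenvector``.

    ``component`` is 0-based; ``base_coords`` has one triple per selection
    site; default scalars are 21 evenly spaced values in [-5, +5].
    """
    if component >= model.eigenvectors.shape[0]:
        raise PCAError(f"component {component} out of range")
    lam = model.eigenvalues[component]
    if lam <= max(1e-12, 1e-10 * float(model.eigenvalues[0])):
        raise PCAError(f"component {component} has zero eigenvalue; no motion")
    if scalars is None:
        scalars = np.linspace(-5.0, 5.0, 21)
    base = np.asarray(base_coords, dtype=float)
    n = model.mean_coords.shape[0] // 3
    if base.shape != (n, 3):
        raise PCAError(f"base coords shape {base.shape} != ({n}, 3)")
    v = model.eigenvectors[component].reshape(n, 3)
    return base[None] + np.asarray(scalars)[:, None, None] * np.sqrt(lam) * v[None]


def write_mode_animation(system: MolecularSystem, model: PCAModel,
                         frames: np.ndarray, path: str) -> None:
    """Write animation frames as a multi-model PDB on the selection atoms."""
    sub = _subsystem(system, model.atom_indices)
    write_pdb(sub, path, frames=frames)


def _subsystem(system: MolecularSystem, atoms: np.ndarray) -> MolecularSystem:
    return MolecularSystem(
        atom_names=system.atom_names[atoms],
        elements=system.elements[atoms],
        residue_numbers=system.residue_numbers[atoms],
        residue_names=system.residue_names[atoms],
        chain_ids=system.chain_ids[atoms],
        masses=system.masses[atoms],
        reference_coords=system.reference_coords[atoms],
    )


# ---------------------------------------------------------------------------
# free-energy landscapes
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergyLandscape:
    axes: tuple[int, int]
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray        # (nx, ny) ints
    free_energy: np.ndarray   # (nx, ny) in kT; +inf on unsampled bins
    temperature_kt: float = 1.0

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    @property
    def bin_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0])
                     * (self.y_edges[1] - self.y_edges[0]))

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return (0.5 * (self.x_edges[:-1] + self.x_edges[1:]),
                0.5 * (self.y_edges[:-1] + self.y_edges[1:]))

    def write_tsv(self, path: str) -> None:
        cx, cy = self.bin_centers()
        with open(path, "w") as fh:
            fh.write("bin_x_center\tbin_y_center\tcount\tF_kT\n")
            for i in range(len(cx)):
                for j in range(len(cy)):
                    f = self.free_energy[i, j]
                    fs = f"{f:.6f}" if np.isfinite(f) else "inf"
                    fh.write(f"{cx[i]:.6f}\t{cy[j]:.6f}\t"
                             f"{self.counts[i, j]}\t{fs}\n")


def free_energy_landscape(projections: np.ndarray,
                          bins: int | tuple = 50,
                          padding: float = 0.05,
                          temperature_kt: float = 1.0,
                          axes: tuple[int, int] = (0, 1),
                          edges: tuple[np.ndarray, np.ndarray] | None = None
                          ) -> FreeEnergyLandscape:
    """Binned -kT ln(density) surface over 2D projections.

    The data range is padded by ``padding`` on each axis unless explicit
    ``edges`` are given. F is normalised by the max bin count so the minimum
    over occupied bins is 0; unsampled bins carry +inf.
    """
    p = np.asarray(projections, dtype=float)
    if p.ndim != 2 or p.shape[1] < 2:
        raise PCAError("projections must be (frames, >=2)")
    if p.shape[0] < 100:
        import warnings
        warnings.warn(f"only {p.shape[0]} frames; landscape will be noisy",
                      stacklevel=2)
    x, y = p[:, axes[0]], p[:, axes[1]]
    if edges is None:
        def pad(v):
            lo, hi = float(v.min()), float(v.max())
            span = (hi - lo) or 1.0
            return lo - padding * span, hi + padding * span
        (x0, x1), (y0, y1) = pad(x), pad(y)
        counts, xe, ye = np.histogram2d(x, y, bins=bins,
                                        range=[[x0, x1], [y0, y1]])
    else:
        counts, xe, ye = np.histogram2d(x, y, bins=[edges[0], edges[1]])
    counts = counts.astype(int)
    if np.count_nonzero(counts) < 2:
        raise PCAError("fewer than 2 occupied bins; cannot map a landscape")
    fe = np.full(counts.shape, np.inf)
    occ = counts > 0
    fe[occ] = -temperature_kt * np.log(counts[occ] / counts.max())
    return FreeEnergyLandscape(axes=axes, x_edges=xe, y_edges=ye,
                               counts=counts, free_energy=fe,
                               temperature_kt=temperature_kt)


@dataclass
class Basin:
    basin_id: int
    min_f: float
    min_bin: tuple[int, int]
    bins: list[tuple[int, int]]

    @property
    def n_bins(self) -> int:
        return len(self.bins)


@dataclass
class BasinSet:
    basins: list[Basin]
    labels: np.ndarray                     # (nx, ny); -1 outside occupied bins
    barriers: dict[tuple[int, int], float | None]  # None = not accessible
    occupied_area: float

    @property
    def n_basins(self) -> int:
        return len(self.basins)

    def barrier(self, i: int, j: int) -> float | None:
        return self.barriers.get((min(i, j), max(i, j)))

    def report(self, fel: FreeEnergyLandscape) -> dict:
        cx, cy = fel.bin_centers()
        return {
            "n_basins": self.n_basins,
            "occupied_area": self.occupied_area,
            "basins": [
                {"id": b.basin_id, "min_F_kT": b.min_f, "n_bins": b.n_bins,
                 "location": [float(cx[b.min_bin[0]]), float(cy[b.min_bin[1]])]}
                for b in self.basins
            ],
            "barriers": [
                {"pair": list(k), "height_kT": v}
                for k, v in sorted(self.barriers.items())
            ],
        }


_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
              if (di, dj) != (0, 0)]


def find_basins(fel: FreeEnergyLandscape, min_depth: float = 1.0,
                min_count: int = 10) -> BasinSet:
    """Watershed segmentation of the occupied-bin graph with persistence
    merging and bottleneck barriers.

    Bins with at least ``min_count`` samples are flooded in order of
    increasing F (ties broken by bin index, so the result is deterministic);
    more weakly sampled bins carry too much log-count noise to segment. A bin meeting no labelled
    neighbour seeds a new basin; a bin joining catchments of several basins is
    a saddle. A basin shallower than ``min_depth`` at its first saddle is
    merged into the deeper basin there (its lowest-barrier neighbour, since
    flooding is monotone). The first level at which two surviving basins'
    catchments connect is the minimax (bottleneck) path height between them;
    ``barrier(i, j)`` = that level minus ``min(F_i*, F_j*)``. Basins in
    disconnected occupied regions get barrier ``None`` (not accessible).
    """
    occ = fel.counts >= max(1, min_count)
    fgrid = fel.free_energy
    nx, ny = occ.shape
    order = sorted(((fgrid[i, j], i, j)
                    for i in range(nx) for j in range(ny) if occ[i, j]))

    labels = -np.ones((nx, ny), dtype=int)
    parent: dict[int, int] = {}
    min_f: dict[int, float] = {}
    min_bin: dict[int, tuple[int, int]] = {}
    saddles: dict[tuple[int, int], float] = {}
    next_id = 0

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for f, i, j in order:
        roots = []
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny and labels[ni, nj] >= 0:
                r = find(labels[ni, nj])
                if r not in roots:
                    roots.append(r)
        if not roots:
            labels[i, j] = next_id
            parent[next_id] = next_id
            min_f[next_id] = f
            min_bin[next_id] = (i, j)
            next_id += 1
            continue
        if len(roots) > 1:
            # saddle: order by basin depth (deepest survives a merge)
            roots.sort(key=lambda r: (min_f[r], min_bin[r]))
            survivor = roots[0]
            for r in roots[1:]:
                depth = f - min_f[r]
                if depth < min_depth:
                    parent[r] = survivor  # too shallow: absorb
            survivors = sorted({find(r) for r in roots})
            for ia_, ra in enumerate(survivors):
                for rb in survivors[ia_ + 1:]:
                    key = (min(ra, rb), max(ra, rb))
                    if key not in saddles:
                        saddles[key] = f
            roots = [find(survivor)]
        labels[i, j] = roots[0]

    # drop basins that are shallow relative to their own connected component
    # (isolated low-count speckles at the rim of the sampled region would
    # otherwise each count as a "basin")
    from scipy import ndimage
    comp, _n_comp = ndimage.label(occ, structure=np.ones((3, 3), dtype=int))
    comp_max: dict[int, float] = {}
    for i in range(nx):
        for j in range(ny):
            if occ[i, j]:
                c = int(comp[i, j])
                comp_max[c] = max(comp_max.get(c, -np.inf), fgrid[i, j])
    kept = []
    for r in sorted({find(r) for r in parent}):
        c = int(comp[min_bin[r]])
        if comp_max[c] - min_f[r] >= min_depth or min_f[r] == 0.0:
            kept.append(r)
    final_roots = sorted(set(kept))
    remap = {r: k for k, r in enumerate(final_roots)}
    basin_bins: dict[int, list[tuple[int, int]]] = {k: [] for k in remap.values()}
    for i in range(nx):
        for j in range(ny):
            if labels[i, j] >= 0:
                root = find(labels[i, j])
                if root in remap:
                    k = remap[root]
                    labels[i, j] = k
                    basin_bins[k].append((i, j))
                else:
                    labels[i, j] = -1  # speckle component, not a basin
    basins = [Basin(basin_id=k, min_f=min_f[r], min_bin=min_bin[r],
                    bins=basin_bins[k])
              for r, k in remap.items()]
    basins.sort(key=lambda b: b.basin_id)

    # saddles between roots that later merged map onto final basins; keep the
    # lowest recorded connection level per final pair
    barriers: dict[tuple[int, int], float | None] = {}
    lowest: dict[tuple[int, int], float] = {}
    for (a, b), level in saddles.items():
        ra, rb = find(a), find(b)
        if ra not in remap or rb not in remap:
            continue
        ka, kb = remap[ra], remap[rb]
        if ka == kb:
            continue
        key = (min(ka, kb), max(ka, kb))
        if key not in lowest or level < lowest[key]:
            lowest[key] = level
    for ka in range(len(basins)):
        for kb in range(ka + 1, len(basins)):
            key = (ka, kb)
            if key in lowest:
                barriers[key] = float(
                    lowest[key] - min(basins[ka].min_f, basins[kb].min_f))
            else:
                barriers[key] = None  # disconnected occupied regions
    area = float(np.count_nonzero(fel.occupied)) * fel.bin_area
    return BasinSet(basins=basins, labels=labels, barriers=barriers,
                    occupied_area=area)


def fel_from_trajectory(traj: TrajectorySegment, selection: SiteSelection,
                        bins: int = 50, temperature_kt: float = 1.0
                        ) -> tuple[PCAModel, np.ndarray, FreeEnergyLandscape]:
    """Convenience: PCA -> top-2 projection -> landscape."""
    model = fit_pca(traj, selection)
    proj = project_frames(traj, model, k=2)
    fel = free_energy_landscape(proj, bins=bins, temperature_kt=temperature_kt)
    return model, proj, fel
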