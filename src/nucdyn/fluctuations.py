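"""Local-fluctuation analysis: per-site RMSF, the trajectory-thirds
significance procedure, two-system comparison, and DNA basepair RMSF.

RMSF of a site (a group of atoms) is the square root of the mean over frames
of the mean over the group's atoms of the squared displacement from the
reference position. The significance threshold for comparing two systems is
twice the maximum per-third standard deviation across both systems (the
"~0.3 A -> 0.6 A" rule generalised).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (MolecularSystem, NucleosomeAnnotation, SiteSelection,
                   TrajectorySegment, select_sites)
from .geometry import average_structure

__all__ = ["RMSFProfile", "RMSFComparison", "site_rmsf", "compare_rmsf",
           "basepair_rmsf"]


@dataclass
class RMSFProfile:
    sites: list[str]
    rmsf: np.ndarray                 # (n_sites,)
    third_rmsf: np.ndarray | None    # (n_sites, 3)
    third_sd: np.ndarray | None      # (n_sites,)
    threshold: float | None          # 2 * max per-site third SD

    def __post_init__(self) -> None:
        if np.any(self.rmsf < 0):
            raise ValueError("rmsf must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("site\trmsf_A\tthird1\tthird2\tthird3\tthird_sd\tthreshold\n")
            for i, s in enumerate(self.sites):
                if self.third_rmsf is not None:
                    t = self.third_rmsf[i]
                    fh.write(f"{s}\t{self.rmsf[i]:.6f}\t{t[0]:.6f}\t{t[1]:.6f}"
                             f"\t{t[2]:.6f}\t{self.third_sd[i]:.6f}"
                             f"\t{self.threshold:.6f}\n")
                else:
                    fh.write(f"{s}\t{self.rmsf[i]:.6f}\t\t\t\t\t\n")


@dataclass
class RMSFComparison:
    """Per-site RMSF difference (B - A) with significance flags."""

    sites: list[str]
    delta: np.ndarray
    significant: np.ndarray          # bool per site
    threshold: float                 # max of the two profiles' thresholds
    extrema: dict[str, tuple[str, float]]  # region -> (site, signed delta)
    unmapped_a: list[str]
    unmapped_b: list[str]

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("site\tdelta_A\tsignificant\n")
            for s, d, f in zip(self.sites, self.delta, self.significant):
                fh.write(f"{s}\t{d:.6f}\t{int(f)}\n")


def _group_rmsf(coords: np.ndarray, groups: list[np.ndarray],
                reference: np.ndarray) -> np.ndarray:
    """RMSF per group: sqrt(mean over frames and group atoms of |x - ref|^2)."""
    disp2 = np.sum((coords - reference[None]) ** 2, axis=2)  # (F, n_atoms_sel)
    msd_per_atom = disp2.mean(axis=0)
    return np.sqrt(np.array([msd_per_atom[g].mean() for g in groups]))


def site_rmsf(traj: TrajectorySegment, selection: SiteSelection,
              reference: np.ndarray | None = None,
              thirds: bool = True) -> RMSFProfile:
    """Per-site RMSF over the analysis window, with per-third estimates.

    ``reference`` defaults to the window average (full-system coordinates or
    selection-sized). Thirds split the window into three equal contiguous
    frame blocks (remainder frames dropped from the end); each third is
    measured against its own block average so every estimate is internally
    centred. Requires >= 2 frames; thirds require >= 3 frames per third.
    """
    if traj.n_window_frames < 2:
        raise ValueError("RMSF requires at least 2 frames in the window")
    # map global atom indices to positions within the packed selection array
    flat = np.unique(np.concatenate(selection.groups))
    pos = {int(a): i for i, a in enumerate(flat)}
    groups = [np.array([pos[int(a)] for a in g]) for g in selection.groups]
    coords = traj.window_coords()[:, flat]
    if reference is None:
        ref = coords.mean(axis=0)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape[0] == traj.n_atoms:
            ref = reference[flat]
        elif reference.shape[0] == flat.size:
            ref = reference
        else:
            raise ValueError("reference must cover the system or the selection")
    full = _group_rmsf(coords, groups, ref)

    third_rmsf = third_sd = threshold = None
    if thirds:
        n3 = traj.n_window_frames // 3
        if n3 < 3:
            raise ValueError(
                f"thirds need >= 3 frames per third, window has "
                f"{traj.n_window_frames} frames")
        cols = []
        for k in range(3):
            block = coords[k * n3:(k + 1) * n3]
            cols.append(_group_rmsf(block, groups, block.mean(axis=0)))
        third_rmsf = np.stack(cols, axis=1)
        third_sd = third_rmsf.std(axis=1, ddof=1)
        threshold = float(2.0 * third_sd.max())
    return RMSFProfile(sites=list(selection.site_labels), rmsf=full,
                       third_rmsf=third_rmsf, third_sd=third_sd,
                       threshold=threshold)


def compare_rmsf(profile_a: RMSFProfile, profile_b: RMSFProfile,
                 site_map: list[tuple[str, str]] | None = None,
                 regions: dict[str, list[str]] | None = None) -> RMSFComparison:
    """Per-site RMSF difference B - A with significance flags.

    ``site_map`` pairs site labels of A with site labels of B for chains of
    unequal length (e.g. a loop insertion); by default sites are matched by
    identical label. Unmapped sites are reported, never silently dropped.
    ``regions`` maps a region name to the list of (A-side) site labels it
    covers; the signed delta at the largest-|delta| site is reported per
    region.
    """
    ia = {s: i for i, s in enumerate(profile_a.sites)}
    ib = {s: i for i, s in enumerate(profile_b.sites)}
    if site_map is None:
        shared = [s for s in profile_a.sites if s in ib]
        pairs = [(s, s) for s in shared]
    else:
        pairs = list(site_map)
        for sa, sb in pairs:
            if sa not in ia:
                raise KeyError(f"site {sa!r} not in profile A")
            if sb not in ib:
                raise KeyError(f"site {sb!r} not in profile B")
    mapped_a = {sa for sa, _ in pairs}
    mapped_b = {sb for _, sb in pairs}
    unmapped_a = [s for s in profile_a.sites if s not in mapped_a]
    unmapped_b = [s for s in profile_b.sites if s not in mapped_b]

    delta = np.array([profile_b.rmsf[ib[sb]] - profile_a.rmsf[ia[sa]]
                      for sa, sb in pairs])
    thr_a = profile_a.threshold if profile_a.threshold is not None else 0.0
    thr_b = profile_b.threshold if profile_b.threshold is not None else 0.0
    threshold = float(max(thr_a, thr_b))
    significant = np.abs(delta) > threshold

    sites = [sa for sa, _ in pairs]
    extrema: dict[str, tuple[str, float]] = {}
    if regions:
        site_idx = {s: i for i, s in enumerate(sites)}
        for name, labels in regions.items():
            idx = [site_idx[s] for s in labels if s in site_idx]
            if not idx:
                continue
            best = idx[int(np.argmax(np.abs(delta[idx])))]
            extrema[name] = (sites[best], float(delta[best]))
    return RMSFComparison(sites=sites, delta=delta, significant=significant,
                          threshold=threshold, extrema=extrema,
                          unmapped_a=unmapped_a, unmapped_b=unmapped_b)


def basepair_rmsf(traj: TrajectorySegment, system: MolecularSystem,
                  annotation: NucleosomeAnnotation,
                  atom_class: str = "heavy",
                  per_strand: bool = False,
                  thirds: bool = True,
                  reference: np.ndarray | None = None):
    """DNA basepair RMSF, ordered by basepair index.

    The trajectory should be aligned on the protein core so DNA motion is
    measured relative to the core. Default sites pool the heavy atoms of both
    paired nucleotides; ``atom_class='phosphate'`` restricts to P atoms;
    ``per_strand=True`` returns (strand-I profile, strand-J profile) instead,
    mirroring a two-line per-strand plot.
    """
    if not annotation.has_dna:
        raise ValueError("basepair RMSF requires both DNA strands annotated")
    if not per_strand:
        sel = select_sites(system, annotation, atom_class="basepair")
        if atom_class == "phosphate":
            p_mask = system.atom_names == "P"
            groups = [g[p_mask[g]] for g in sel.groups]
            sel = SiteSelection(label=sel.label, groups=groups,
                                site_labels=sel.site_labels, grouping="basepair")
        return site_rmsf(traj, sel, reference=reference, thirds=thirds)

    chain_i = annotation.role_chain("DNA-I")
    chain_j = annotation.role_chain("DNA-J")
    res_i = system.chain_residues(chain_i)
    res_j = system.chain_residues(chain_j)
    mask = (system.atom_names == "P") if atom_class == "phosphate" \
        else system.heavy_mask()
    profiles = []
    for chain, res, mapper in (
            (chain_i, res_i, lambda b: annotation.bp_to_strand_positions(b)[0]),
            (chain_j, res_j, lambda b: annotation.bp_to_strand_positions(b)[1])):
        groups, labels = [], []
        for b in annotation.bp_indices:
            g = system.residue_atoms(chain, res[mapper(int(b))])
            g = g[mask[g]]
            groups.append(np.sort(g))
            labels.append(f"bp{int(b):+d}")
        sel = SiteSelection(label=f"{chain} basepair sites", groups=groups,
                            site_labels=labels, grouping="basepair")
        profiles.append(site_rmsf(traj, sel, reference=reference, thirds=thirds))
    return tuple(profiles)


def rmsf_reference(traj: TrajectorySegment) -> np.ndarray:
    """Convenience: the geometric average structure used as RMSF reference."""
    return average_structure(traj)
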