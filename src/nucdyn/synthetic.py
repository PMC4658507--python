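"""Toy nucleosome-like systems and trajectories with planted ground truth.

The generator plants statistics, not physics: Cα-only protein chains on an
inner cylinder, pseudo-nucleotides (three dummy heavy atoms each) on an outer
DNA superhelix, and trajectories with prescribed Gaussian site noise, low-rank
collective modes, two-state switching, or scripted detachment events. Every
generator is bit-reproducible given its seed; the single root seed is expanded
into independent per-purpose streams so adding one noise source never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (MolecularSystem, NucleosomeAnnotation, TrajectorySegment,
                   annotate_nucleosome)

__all__ = [
    "ToyGeometry", "ToySpec",
    "build_toy_nucleosome", "gaussian_fluctuation_traj", "planted_mode_traj",
    "two_state_traj", "detachment_scenario_traj", "random_modes",
    "DEFAULT_ROLE_CHAINS",
]

DEFAULT_ROLE_CHAINS = {
    "H3-like": "A", "H4": "B", "H2A": "C", "H2B": "D",
    "H3-like'": "E", "H4'": "F", "H2A'": "G", "H2B'": "H",
    "DNA-I": "I", "DNA-J": "J",
}

_NT_OFFSETS = np.array([[0.0, 0.0, 0.0],   # P-like
                        [1.5, 0.0, 0.5],   # C1'-like
                        [0.5, 1.5, -0.5]])  # N1-like
_NT_NAMES = ("P", "C1'", "N1")
_NT_ELEMENTS = ("P", "C", "N")


@dataclass(frozen=True)
class ToyGeometry:
    dna_radius: float = 41.8       # superhelix radius, A
    dna_pitch: float = 25.9        # rise per superhelical turn, A
    dna_turns: float = 1.65        # total wrap for the full basepair count
    protein_radius: float = 38.0   # toy core sits just inside the DNA wrap
    strand_offset: float = 3.0     # half-separation of paired strands, A
    jitter_sigma: float = 0.1      # deterministic seed-dependent jitter, A


@dataclass
class ToySpec:
    """Declarative description of a toy system (see module docstring)."""

    chains: list[tuple[str, int]]  # (role, n_residues or n_nucleotides)
    geometry: ToyGeometry = field(default_factory=ToyGeometry)
    seed: int = 0


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def build_toy_nucleosome(spec: ToySpec
                         ) -> tuple[MolecularSystem, NucleosomeAnnotation]:
    """Build a toy system and its auto-generated annotation.

    Protein chains are Cα-only (alanine) on the inner cylinder; DNA strands
    are paired pseudo-nucleotides on the outer superhelix with the dyad at the
    strand midpoint. Deterministic given (spec, seed).
    """
    roles = [r for r, _ in spec.chains]
    if len(roles) != len(set(roles)):
        raise ValueError("duplicate roles in toy spec")
    dna = {r: n for r, n in spec.chains if r.startswith("DNA")}
    protein = [(r, n) for r, n in spec.chains if not r.startswith("DNA")]
    if not protein:
        raise ValueError("at least one protein chain required")
    if dna and (set(dna) != {"DNA-I", "DNA-J"} or dna["DNA-I"] != dna["DNA-J"]):
        raise ValueError("DNA requires two equal-length strands DNA-I and DNA-J")
    geo = spec.geometry
    rng = _streams(spec.seed, 1)[0]

    names, elements, resnums, resnames, chains, coords = [], [], [], [], [], []

    def add_atom(name, el, resnum, resname, chain, xyz):
        names.append(name)
        elements.append(el)
        resnums.append(resnum)
        resnames.append(resname)
        chains.append(chain)
        coords.append(xyz)

    # protein chains: Calpha trace spiralling on the inner cylinder, each
    # chain phase-shifted so chains do not overlap
    z_span = geo.dna_pitch * geo.dna_turns * 0.7  # keep the core inside the wrap
    for ci, (role, n_res) in enumerate(protein):
        chain = DEFAULT_ROLE_CHAINS[role]
        phase = 2 * np.pi * ci / max(len(protein), 1)
        for k in range(n_res):
            theta = phase + 0.4 * k
            z = -z_span / 2 + z_span * k / max(n_res - 1, 1)
            xyz = np.array([geo.protein_radius * np.cos(theta),
                            geo.protein_radius * np.sin(theta), z])
            add_atom("CA", "C", k + 1, "ALA", chain, xyz)

    # DNA superhelix with the dyad at bp index (L-1)//2
    if dna:
        L = dna["DNA-I"]
        dyad = (L - 1) // 2
        total_angle = 2 * np.pi * geo.dna_turns
        bp_centers, bp_normals = [], []
        for i in range(L):
            t = (i - dyad) / max(L - 1, 1)  # -0.5..+0.5 around the dyad
            theta = total_angle * t
            z = geo.dna_pitch * geo.dna_turns * t
            center = np.array([geo.dna_radius * np.cos(theta),
                               geo.dna_radius * np.sin(theta), z])
            normal = np.array([0.0, 0.0, 1.0])  # strand separation along z
            bp_centers.append(center)
            bp_normals.append(normal)
        # strand I: positions 0..L-1 in order
        for i in range(L):
            site = bp_centers[i] + geo.strand_offset * bp_normals[i]
            base = "DA" if i % 2 == 0 else "DG"
            for nm, el, off in zip(_NT_NAMES, _NT_ELEMENTS, _NT_OFFSETS):
                add_atom(nm, el, i + 1, base, DEFAULT_ROLE_CHAINS["DNA-I"],
                         site + off)
        # strand J is antiparallel: its position k carries basepair L-1-k
        for k in range(L):
            i = L - 1 - k
            site = bp_centers[i] - geo.strand_offset * bp_normals[i]
            base = "DT" if i % 2 == 0 else "DC"
            for nm, el, off in zip(_NT_NAMES, _NT_ELEMENTS, _NT_OFFSETS):
                add_atom(nm, el, k + 1, base, DEFAULT_ROLE_CHAINS["DNA-J"],
                         site + off)

    xyz = np.asarray(coords) + rng.normal(0.0, geo.jitter_sigma,
                                          (len(coords), 3))
    from .core import ATOMIC_MASSES
    system = MolecularSystem(
        atom_names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        residue_numbers=np.asarray(resnums, dtype=int),
        residue_names=np.asarray(resnames, dtype=object),
        chain_ids=np.asarray(chains, dtype=object),
        masses=np.asarray([ATOMIC_MASSES[e] for e in elements], dtype=float),
        reference_coords=xyz,
    )
    chain_roles = {DEFAULT_ROLE_CHAINS[r]: r for r, _ in spec.chains}
    annotation = annotate_nucleosome(system, {"chain_roles": chain_roles})
    return system, annotation


def _times(n_frames: int, dt_ns: float = 0.01) -> np.ndarray:
    return np.arange(n_frames, dtype=float) * dt_ns


def gaussian_fluctuation_traj(system: MolecularSystem,
                              sigma: float | np.ndarray,
                              n_frames: int, seed: int) -> TrajectorySegment:
    """Reference + iid isotropic Gaussian noise per atom; no rigid-body drift.

    ``sigma`` is a scalar or per-atom array of per-coordinate standard
    deviations (so the expected site RMSF is sigma * sqrt(3)).
    """
    sig = np.broadcast_to(np.asarray(sigma, dtype=float),
                          (system.n_atoms,)).copy()
    if np.any(sig < 0):
        raise ValueError("sigma must be non-negative")
    rng = _streams(seed, 2)[1]
    noise = rng.normal(0.0, 1.0, (n_frames, system.n_atoms, 3)) \
        * sig[None, :, None]
    coords = system.reference_coords[None] + noise
    return TrajectorySegment(coords=coords, times=_times(n_frames),
                             window=(0, n_frames), aligned=True)


def random_modes(n_atoms: int, k: int, seed: int) -> np.ndarray:
    """k orthonormal random 3N-vectors (rows)."""
    rng = _streams(seed, 3)[2]
    m = rng.normal(size=(3 * n_atoms, k))
    q, _ = np.linalg.qr(m)
    return q.T[:k]


def _orthonormalize(vectors: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(vectors.T)
    # keep the original orientation of each vector
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return (q * signs).T


def planted_mode_traj(system: MolecularSystem,
                      modes: list[tuple[np.ndarray, float]],
                      n_frames: int, seed: int,
                      floor_sigma: float = 0.0) -> TrajectorySegment:
    """Reference + low-rank collective motion along planted orthonormal modes.

    ``modes`` is a list of (3N-vector, variance) pairs; vectors are
    orthonormalised internally (QR, original orientation kept). Amplitudes
    are iid Normal(0, variance) per frame, plus an optional isotropic floor.
    """
    d = 3 * system.n_atoms
    if len(modes) > d:
        raise ValueError(f"more modes ({len(modes)}) than coordinates ({d})")
    vecs = np.stack([np.asarray(v, dtype=float).reshape(d) for v, _ in modes])
    variances = np.asarray([lam for _, lam in modes], dtype=float)
    if np.any(variances < 0):
        raise ValueError("variances must be non-negative")
    vecs = _orthonormalize(vecs)
    rng_a, rng_floor = _streams(seed, 2)
    amps = rng_a.normal(0.0, 1.0, (n_frames, len(modes))) * np.sqrt(variances)
    disp = amps @ vecs  # (n_frames, 3N)
    if floor_sigma > 0:
        disp = disp + rng_floor.normal(0.0, floor_sigma, disp.shape)
    coords = system.reference_coords[None] + disp.reshape(n_frames, -1, 3)
    return TrajectorySegment(coords=coords, times=_times(n_frames),
                             window=(0, n_frames), aligned=True)


def two_state_traj(system: MolecularSystem, offset_coords: np.ndarray,
                   p_switch: float, n_frames: int, seed: int,
                   floor_sigma: float = 0.1
                   ) -> tuple[TrajectorySegment, np.ndarray]:
    """Markov switching between the reference and reference + offset.

    Returns the trajectory and the true per-frame state labels (0/1). The
    initial state is drawn from the stationary (uniform) distribution.
    """
    if not 0 < p_switch < 1:
        raise ValueError("p_switch must be in (0, 1)")
    offset = np.asarray(offset_coords, dtype=float)
    if offset.shape != system.reference_coords.shape:
        raise ValueError("offset must be (n_atoms, 3)")
    if not np.any(offset):
        import warnings
        warnings.warn("zero offset: the two states are degenerate",
                      stacklevel=2)
    rng_state, rng_noise = _streams(seed, 2)
    labels = np.empty(n_frames, dtype=int)
    labels[0] = rng_state.integers(0, 2)
    flips = rng_state.random(n_frames - 1) < p_switch
    for t in range(1, n_frames):
        labels[t] = labels[t - 1] ^ int(flips[t - 1])
    coords = np.repeat(system.reference_coords[None], n_frames, axis=0)
    coords[labels == 1] += offset
    if floor_sigma > 0:
        coords = coords + rng_noise.normal(0.0, floor_sigma, coords.shape)
    traj = TrajectorySegment(coords=coords, times=_times(n_frames),
                             window=(0, n_frames), aligned=True)
    return traj, labels


def detachment_scenario_traj(system: MolecularSystem,
                             annotation: NucleosomeAnnotation,
                             bp_range: tuple[int, int],
                             event_frames: tuple[int, int],
                             displacement: float,
                             n_frames: int, seed: int,
                             swing: tuple[tuple[str, int], int, int] | None = None,
                             floor_sigma: float = 0.05
                             ) -> tuple[TrajectorySegment, dict]:
    """Scripted DNA-segment detachment with an optional lagged residue swing.

    During ``event_frames`` (half-open), the atoms of basepairs
    ``bp_range[0]..bp_range[1]`` (inclusive) are displaced radially outward
    (in the xy-plane, away from the superhelix axis) by ``displacement`` A.
    ``swing = (residue, lag, target_bp)`` moves the residue's atoms next to
    the target basepair starting ``lag`` frames after event start. Returns the
    trajectory and a ground-truth table.
    """
    s, e = event_frames
    if not (0 <= s < e <= n_frames):
        raise ValueError(f"event frames [{s}, {e}) outside trajectory")
    b0, b1 = bp_range
    from .core import select_sites
    sel = select_sites(system, annotation, atom_class="basepair",
                       bp=list(range(b0, b1 + 1)), pooled=True)
    bp_atoms = sel.groups[0]

    rng_noise, = _streams(seed, 1)
    coords = np.repeat(system.reference_coords[None], n_frames, axis=0)
    # radial outward displacement in xy from the z axis
    xy = system.reference_coords[bp_atoms, :2]
    norms = np.linalg.norm(xy, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    direction = np.concatenate([xy / norms, np.zeros((len(bp_atoms), 1))], axis=1)
    coords[s:e, bp_atoms] = coords[s:e, bp_atoms] \
        + displacement * direction[None]

    truth: dict = {"detach_frames": (s, e), "bp_range": (b0, b1),
                   "displacement_A": displacement}
    if swing is not None:
        (res_chain, res_num), lag, target_bp = swing
        if lag < 0:
            raise ValueError("swing lag must be >= 0")
        swing_atoms = system.residue_atoms(res_chain, res_num)
        if np.intersect1d(swing_atoms, bp_atoms).size:
            raise ValueError("swing residue overlaps the displaced basepairs")
        tsel = select_sites(system, annotation, atom_class="basepair",
                            bp=[target_bp], pooled=True)
        s_sw = min(s + lag, n_frames - 1)
        # chase the target where it actually is during the event (it may be
        # part of the displaced segment)
        target_center = coords[s_sw, tsel.groups[0]].mean(axis=0)
        res_center = system.reference_coords[swing_atoms].mean(axis=0)
        shift = target_center - res_center
        # park the residue 2 A short of the target so distances are small
        # but non-zero
        nrm = np.linalg.norm(shift)
        if nrm > 2.0:
            shift = shift * (1.0 - 2.0 / nrm)
        coords[s_sw:e, swing_atoms] = coords[s_sw:e, swing_atoms] + shift[None]
        truth["swing_frames"] = (s_sw, e)
        truth["swing_residue"] = (res_chain, res_num)
        truth["swing_target_bp"] = target_bp
        truth["swing_lag"] = lag
    if floor_sigma > 0:
        coords = coords + rng_noise.normal(0.0, floor_sigma, coords.shape)
    traj = TrajectorySegment(coords=coords, times=_times(n_frames),
                             window=(0, n_frames), aligned=True)
    return traj, truth
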