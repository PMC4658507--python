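"""Fractional contact maps, interface contact counting, minimum-distance
series, and salt-bridge tracking.

A contact exists in a frame iff the minimum distance between heavy atoms of
two residues is strictly less than the cutoff (default 3.6 A). Fractions are
contact frames divided by window frames. Salt bridges use a 4.0 A cutoff on
charged head-group atoms, with an optional charge-center (Arg CZ <-> Glu CD)
variant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .core import MolecularSystem, TrajectorySegment
from .geometry import DistanceSeries

__all__ = [
    "ContactSpec", "ContactMap", "SaltBridgeSpec",
    "contact_map", "interface_contact_count", "min_distance_series",
    "salt_bridge_series", "compare_contact_maps",
]

ResidueId = tuple[str, int]  # (chain, resnum)


class ContactError(ValueError):
    pass


@dataclass(frozen=True)
class ContactSpec:
    cutoff: float = 3.6          # Angstrom, strict less-than
    atom_class: str = "heavy"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ContactError("cutoff must be positive")


# head-group atoms carrying the formal charge
_DONOR_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
_ACCEPTOR_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
# single charge-center atoms (Arg CZ <-> Glu CD convention)
_CHARGE_CENTER = {"ARG": ("CZ",), "LYS": ("NZ",),
                  "GLU": ("CD",), "ASP": ("CG",)}


@dataclass(frozen=True)
class SaltBridgeSpec:
    cutoff: float = 4.0
    mode: str = "headgroup"  # or "charge_center"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ContactError("cutoff must be positive")
        if self.mode not in ("headgroup", "charge_center"):
            raise ContactError(f"unknown salt-bridge mode {self.mode!r}")


@dataclass
class ContactMap:
    """Fraction-of-time contact occupancy per residue pair.

    Only pairs with non-zero fraction are stored; absent pairs have
    fraction 0 by definition.
    """

    pairs: list[tuple[ResidueId, ResidueId]]
    fractions: np.ndarray
    counts: np.ndarray
    n_frames: int
    spec: ContactSpec
    min_distances: np.ndarray | None = None

    def fraction(self, a: ResidueId, b: ResidueId) -> float:
        key = (tuple(a), tuple(b))
        for p, f in zip(self.pairs, self.fractions):
            if p == key or p == (key[1], key[0]):
                return float(f)
        return 0.0

    def as_dict(self) -> dict[tuple[ResidueId, ResidueId], float]:
        return {p: float(f) for p, f in zip(self.pairs, self.fractions)}

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chainA\tresA\tchainB\tresB\tfraction\tmin_distance_A\n")
            for i, ((ca, ra), (cb, rb)) in enumerate(self.pairs):
                md = (f"{self.min_distances[i]:.4f}"
                      if self.min_distances is not None else "")
                fh.write(f"{ca}\t{ra}\t{cb}\t{rb}\t{self.fractions[i]:.6f}\t{md}\n")


def _residue_atom_table(system: MolecularSystem, residues: list[ResidueId],
                        atom_class: str = "heavy") -> tuple[np.ndarray, np.ndarray]:
    """Flat atom-index array and parallel residue-ordinal array."""
    if atom_class == "heavy":
        mask = system.heavy_mask()
    elif atom_class == "all":
        mask = np.ones(system.n_atoms, dtype=bool)
    else:
        raise ContactError(f"unsupported atom class {atom_class!r}")
    atoms, owners = [], []
    for k, (chain, resnum) in enumerate(residues):
        g = system.residue_atoms(chain, resnum)
        g = g[mask[g]]
        if g.size == 0:
            raise ContactError(f"residue {chain}:{resnum} has no {atom_class} atoms")
        atoms.append(g)
        owners.append(np.full(g.size, k))
    return np.concatenate(atoms), np.concatenate(owners)


def _frame_contact_pairs(xa: np.ndarray, xb: np.ndarray,
                         owner_a: np.ndarray, owner_b: np.ndarray,
                         cutoff: float) -> set[tuple[int, int]]:
    """Residue-ordinal pairs with any heavy-atom distance strictly < cutoff."""
    ta = cKDTree(xa)
    tb = cKDTree(xb)
    hits = ta.query_ball_tree(tb, r=cutoff)
    out: set[tuple[int, int]] = set()
    for i, js in enumerate(hits):
        if not js:
            continue
        di = np.linalg.norm(xb[js] - xa[i], axis=1)
        for j, d in zip(js, di):
            if d < cutoff:  # strict; query_ball includes the boundary
                out.add((int(owner_a[i]), int(owner_b[j])))
    return out


def contact_map(traj: TrajectorySegment, system: MolecularSystem,
                residues_a: list[ResidueId], residues_b: list[ResidueId],
                spec: ContactSpec = ContactSpec()) -> ContactMap:
    """Fraction-of-time contact map between two disjoint residue sets."""
    if set(map(tuple, residues_a)) & set(map(tuple, residues_b)):
        raise ContactError("residue sets overlap")
    atoms_a, own_a = _residue_atom_table(system, residues_a, spec.atom_class)
    atoms_b, own_b = _residue_atom_table(system, residues_b, spec.atom_class)
    coords = traj.window_coords()
    counter: Counter = Counter()
    for f in range(coords.shape[0]):
        pairs = _frame_contact_pairs(coords[f, atoms_a], coords[f, atoms_b],
                                     own_a, own_b, spec.cutoff)
        counter.update(pairs)
    n = coords.shape[0]
    keys = sorted(counter)
    pairs = [(tuple(residues_a[i]), tuple(residues_b[j])) for i, j in keys]
    counts = np.array([counter[k] for k in keys], dtype=int)
    # whole-window minimum distance per stored pair
    min_d = np.full(len(keys), np.inf)
    if keys:
        key_pos = {k: i for i, k in enumerate(keys)}
        for f in range(n):
            d = cdist(coords[f, atoms_a], coords[f, atoms_b])
            for (i, j), pos in key_pos.items():
                sub = d[np.ix_(own_a == i, own_b == j)]
                m = sub.min()
                if m < min_d[pos]:
                    min_d[pos] = m
    return ContactMap(pairs=pairs, fractions=counts / n, counts=counts,
                      n_frames=n, spec=spec,
                      min_distances=min_d if keys else None)


@dataclass
class ContactCountSeries:
    counts: np.ndarray          # per-frame number of residue pairs in contact
    histogram: dict[int, int]
    mean: float
    times: np.ndarray = field(default_factory=lambda: np.empty(0))


def interface_contact_count(traj: TrajectorySegment, system: MolecularSystem,
                            residues_a: list[ResidueId],
                            residues_b: list[ResidueId],
                            spec: ContactSpec = ContactSpec()) -> ContactCountSeries:
    """Per-frame count of residue pairs in contact across an interface."""
    if set(map(tuple, residues_a)) & set(map(tuple, residues_b)):
        raise ContactError("residue sets overlap")
    atoms_a, own_a = _residue_atom_table(system, residues_a, spec.atom_class)
    atoms_b, own_b = _residue_atom_table(system, residues_b, spec.atom_class)
    coords = traj.window_coords()
    counts = np.empty(coords.shape[0], dtype=int)
    for f in range(coords.shape[0]):
        counts[f] = len(_frame_contact_pairs(
            coords[f, atoms_a], coords[f, atoms_b], own_a, own_b, spec.cutoff))
    hist = dict(sorted(Counter(counts.tolist()).items()))
    return ContactCountSeries(counts=counts, histogram=hist,
                              mean=float(counts.mean()),
                              times=traj.window_times())


def min_distance_series(traj: TrajectorySegment, system: MolecularSystem,
                        residue_a: ResidueId, residue_b: ResidueId,
                        atom_class: str = "heavy",
                        atoms_a: np.ndarray | None = None,
                        atoms_b: np.ndarray | None = None) -> DistanceSeries:
    """Per-frame minimum inter-atom distance between two residues (or
    explicit atom groups)."""
    if atoms_a is None:
        atoms_a, _ = _residue_atom_table(system, [residue_a], atom_class)
    if atoms_b is None:
        atoms_b, _ = _residue_atom_table(system, [residue_b], atom_class)
    coords = traj.window_coords()
    values = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        values[f] = cdist(coords[f, atoms_a], coords[f, atoms_b]).min()
    la = f"{residue_a[0]}:{residue_a[1]}" if residue_a else "groupA"
    lb = f"{residue_b[0]}:{residue_b[1]}" if residue_b else "groupB"
    return DistanceSeries(label=f"min({la}, {lb})", values=values,
                          times=traj.window_times())


def _salt_bridge_atoms(system: MolecularSystem, residue: ResidueId,
                       table: dict[str, tuple[str, ...]]) -> np.ndarray:
    chain, resnum = residue
    g = system.residue_atoms(chain, resnum)
    resname = str(system.residue_names[g[0]])
    if resname not in table:
        raise ContactError(
            f"residue {chain}:{resnum} is {resname}, expected one of "
            f"{sorted(table)}")
    wanted = table[resname]
    sel = g[np.isin(system.atom_names[g], wanted)]
    if sel.size == 0:
        raise ContactError(
            f"residue {chain}:{resnum} ({resname}) lacks atoms {wanted}")
    return sel


def salt_bridge_series(traj: TrajectorySegment, system: MolecularSystem,
                       residue_pos: ResidueId, residue_neg: ResidueId,
                       spec: SaltBridgeSpec = SaltBridgeSpec()
                       ) -> tuple[float, DistanceSeries]:
    """Occupancy and distance series of a salt bridge.

    ``residue_pos`` must be Lys/Arg and ``residue_neg`` Asp/Glu. Formed in a
    frame iff the minimum distance over the spec's atom definition is below
    the cutoff (strict).
    """
    if spec.mode == "headgroup":
        atoms_p = _salt_bridge_atoms(system, residue_pos, _DONOR_ATOMS)
        atoms_n = _salt_bridge_atoms(system, residue_neg, _ACCEPTOR_ATOMS)
    else:
        pos_table = {k: v for k, v in _CHARGE_CENTER.items() if k in ("ARG", "LYS")}
        neg_table = {k: v for k, v in _CHARGE_CENTER.items() if k in ("GLU", "ASP")}
        atoms_p = _salt_bridge_atoms(system, residue_pos, pos_table)
        atoms_n = _salt_bridge_atoms(system, residue_neg, neg_table)
    series = min_distance_series(traj, system, residue_pos, residue_neg,
                                 atoms_a=atoms_p, atoms_b=atoms_n)
    occupancy = float(np.mean(series.values < spec.cutoff))
    return occupancy, series


def compare_contact_maps(map_a: ContactMap, map_b: ContactMap,
                         lost_from: float = 0.5, lost_to: float = 0.05,
                         weakened_drop: float = 0.25
                         ) -> list[dict]:
    """Classify each residue pair as kept / lost / weakened / gained.

    ``lost``: fraction >= ``lost_from`` in A and < ``lost_to`` in B.
    ``weakened``: drop >= ``weakened_drop`` while still present in B.
    ``gained`` is the mirror image of ``lost``. Thresholds are conventions,
    exposed here and in the config.
    """
    fa = {tuple(sorted(p)): f for p, f in map_a.as_dict().items()}
    fb = {tuple(sorted(p)): f for p, f in map_b.as_dict().items()}
    rows = []
    for pair in sorted(set(fa) | set(fb)):
        a = fa.get(pair, 0.0)
        b = fb.get(pair, 0.0)
        if a >= lost_from and b < lost_to:
            status = "lost"
        elif b >= lost_from and a < lost_to:
            status = "gained"
        elif a - b >= weakened_drop and b >= lost_to:
            status = "weakened"
        else:
            status = "kept"
        rows.append({"pair": pair, "fraction_a": a, "fraction_b": b,
                     "status": status})
    return rows
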