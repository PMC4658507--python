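"""Structure/trajectory ingestion and nucleosome-aware annotation and selection.

Conventions used throughout the package:

* coordinates are in Angstrom, times in nanoseconds;
* frames are 0-based, analysis windows are half-open ``[start, end)``;
* a *heavy* atom is any atom whose element is not hydrogen;
* basepair index 0 sits at the pseudo-dyad, negative indices run toward the
  entry DNA and positive indices toward the exit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "MolecularSystem",
    "TrajectorySegment",
    "NucleosomeAnnotation",
    "SiteSelection",
    "HISTONE_ROLES",
    "DNA_ROLES",
    "REGION_PRESETS",
    "read_structure",
    "read_trajectory",
    "annotate_nucleosome",
    "select_sites",
    "window_from_fraction",
    "write_pdb",
    "write_selection_tsv",
    "load_config",
    "infer_element",
]


class InputError(ValueError):
    """Raised for unparseable or inconsistent input files."""


class TopologyError(ValueError):
    """Raised when a trajectory does not match its topology."""


class SelectionError(KeyError):
    """Raised when a selection query resolves to nothing."""


# Standard atomic weights (IUPAC 2021, rounded). Enough for protein/DNA
# systems plus the ions commonly co-crystallised with nucleosomes.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "MN": 54.938, "FE": 55.845, "ZN": 65.38,
    "CU": 63.546, "BR": 79.904, "I": 126.904, "F": 18.998,
}

HISTONE_ROLES = (
    "H3-like", "H3-like'", "H4", "H4'", "H2A", "H2A'", "H2B", "H2B'",
)
DNA_ROLES = ("DNA-I", "DNA-J")
ALL_ROLES = HISTONE_ROLES + DNA_ROLES

# Residue-range presets (inclusive) in the numbering shared by H3 and CENP-A
# family histones; a range is attached only when the annotated chain covers it.
REGION_PRESETS: dict[str, tuple[str, tuple[int, int]]] = {
    "loop1": ("H3-like", (78, 84)),
    "loop1'": ("H3-like'", (78, 84)),
    "CATD": ("H3-like", (75, 114)),
    "CATD'": ("H3-like'", (75, 114)),
    "acidic_patch_span": ("H2A", (87, 100)),
    "acidic_patch_span'": ("H2A'", (87, 100)),
    "H4_alphaN": ("H4", (26, 29)),
    "H4_alphaN'": ("H4'", (26, 29)),
}

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "HSD", "HSE", "HSP", "HID", "HIE", "HIP",
}
_DNA_RESNAMES = {"DA", "DT", "DG", "DC", "DI", "DU", "A", "T", "G", "C", "U"}

# solvent and free ions dropped on read: they are never analysis targets here
# and would corrupt per-chain residue counts
_SKIP_RESNAMES = {
    "HOH", "WAT", "DOD", "SOL", "MN", "CL", "NA", "K", "MG", "ZN", "CD",
    "BR", "IOD", "SO4", "PO4", "GOL", "EDO", "ACT", "NH4",
}


def infer_element(atom_name: str, element_field: str = "") -> str:
    """Resolve an element symbol.

    The PDB element column is authoritative when present; otherwise the first
    alphabetic character of the digit-stripped atom name is used (so ``CA`` is
    carbon, ``1HG2`` is hydrogen, ``OE1`` oxygen).
    """
    el = element_field.strip().upper()
    if el and el in ATOMIC_MASSES:
        return el
    name = atom_name.strip().upper()
    stripped = name.lstrip("0123456789'\"*")
    for ch in stripped:
        if ch.isalpha():
            # two-letter symbols that actually occur in PDB name columns
            two = stripped[:2]
            if two in ("SE", "FE", "ZN", "MG", "MN", "NA", "CL", "BR", "CU") \
                    and two == name[:2] and len(name) >= 2 and not name[0] == "C":
                return two
            return ch
    raise InputError(f"cannot resolve element for atom name {atom_name!r}")


@dataclass
class MolecularSystem:
    """A topology: per-atom identity plus one reference coordinate set."""

    atom_names: np.ndarray        # (n,) str
    elements: np.ndarray          # (n,) str
    residue_numbers: np.ndarray   # (n,) int
    residue_names: np.ndarray     # (n,) str
    chain_ids: np.ndarray         # (n,) str
    masses: np.ndarray            # (n,) float, amu
    reference_coords: np.ndarray  # (n, 3) float, Angstrom

    def __post_init__(self) -> None:
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        n = len(self.atom_names)
        if self.reference_coords.shape != (n, 3):
            raise InputError(
                f"reference_coords shape {self.reference_coords.shape} != ({n}, 3)")
        if np.any(self.masses <= 0):
            bad = int(np.argmax(self.masses <= 0))
            raise InputError(f"non-positive mass for atom index {bad}")
        keys = list(zip(self.chain_ids, self.residue_numbers.tolist(),
                        self.atom_names))
        if len(set(keys)) != n:
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise InputError(
                        f"duplicate atom key (chain, resnum, name) = {k}")
                seen.add(k)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_key(self, i: int) -> tuple[str, int, str]:
        return (str(self.chain_ids[i]), int(self.residue_numbers[i]),
                str(self.atom_names[i]))

    def chains(self) -> list[str]:
        """Chain identifiers in file order."""
        out: list[str] = []
        for c in self.chain_ids:
            if not out or out[-1] != c:
                if c in out:  # non-contiguous chain records still count once
                    continue
                out.append(str(c))
        return out

    def chain_atoms(self, chain: str) -> np.ndarray:
        idx = np.flatnonzero(self.chain_ids == chain)
        if idx.size == 0:
            raise SelectionError(f"no atoms in chain {chain!r}")
        return idx

    def chain_residues(self, chain: str) -> list[int]:
        """Residue numbers of a chain, in file order, deduplicated."""
        idx = self.chain_atoms(chain)
        out: list[int] = []
        for r in self.residue_numbers[idx]:
            if not out or out[-1] != r:
                out.append(int(r))
        return out

    def residue_atoms(self, chain: str, resnum: int) -> np.ndarray:
        idx = np.flatnonzero(
            (self.chain_ids == chain) & (self.residue_numbers == resnum))
        if idx.size == 0:
            raise SelectionError(f"no residue {resnum} in chain {chain!r}")
        return idx

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def is_protein_chain(self, chain: str) -> bool:
        idx = self.chain_atoms(chain)
        names = set(self.residue_names[idx])
        return bool(names & _PROTEIN_RESNAMES)

    def is_dna_chain(self, chain: str) -> bool:
        idx = self.chain_atoms(chain)
        names = set(self.residue_names[idx])
        return bool(names & _DNA_RESNAMES) and not bool(names & _PROTEIN_RESNAMES)


@dataclass
class TrajectorySegment:
    """An ordered stack of coordinate frames with an analysis window."""

    coords: np.ndarray      # (n_frames, n_atoms, 3) Angstrom
    times: np.ndarray       # (n_frames,) ns, strictly increasing
    window: tuple[int, int]  # half-open [start, end)
    aligned: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        if self.coords.shape[0] == 0:
            raise InputError("empty trajectory (no frames)")
        if self.times.shape != (self.coords.shape[0],):
            raise InputError("times length does not match frame count")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("frame times must be strictly increasing")
        s, e = self.window
        if not (0 <= s < e <= self.n_frames):
            raise InputError(f"window {self.window} invalid for {self.n_frames} frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_window_frames(self) -> int:
        return self.window[1] - self.window[0]

    def window_coords(self) -> np.ndarray:
        s, e = self.window
        return self.coords[s:e]

    def window_times(self) -> np.ndarray:
        s, e = self.window
        return self.times[s:e]

    def with_window(self, window: tuple[int, int]) -> "TrajectorySegment":
        return replace(self, window=tuple(window))


def window_from_fraction(n_frames: int, fraction: float) -> tuple[int, int]:
    """Half-open window covering the final ``fraction`` of the frames.

    At least one frame is always retained. A 10-frame trajectory with
    fraction 0.4 yields frames 6..9.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = max(1, int(np.floor(n_frames * fraction)))
    return (n_frames - n, n_frames)


@dataclass
class NucleosomeAnnotation:
    """Chain-to-role map plus named regions and the basepair coordinate system.

    ``dyad_bp_offset`` is the 0-based position of basepair 0 within strand I.
    Strand-I nucleotide at position ``i`` pairs with strand-J nucleotide at
    position ``L - 1 - i``.
    """

    chain_roles: dict[str, str]
    named_regions: dict[str, tuple[str, tuple[int, int]]] = field(default_factory=dict)
    dimers: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_basepairs: int = 0
    dyad_bp_offset: int = 0

    def __post_init__(self) -> None:
        roles = list(self.chain_roles.values())
        if len(roles) != len(set(roles)):
            dup = sorted({r for r in roles if roles.count(r) > 1})
            raise InputError(f"role(s) assigned to more than one chain: {dup}")
        for r in roles:
            if r not in ALL_ROLES:
                raise InputError(f"unknown role {r!r}; valid: {ALL_ROLES}")

    # -- role helpers ------------------------------------------------------
    def role_chain(self, role: str) -> str:
        for chain, r in self.chain_roles.items():
            if r == role:
                return chain
        raise SelectionError(f"role {role!r} not annotated")

    @property
    def has_dna(self) -> bool:
        roles = set(self.chain_roles.values())
        return "DNA-I" in roles and "DNA-J" in roles

    def protein_roles(self) -> list[str]:
        return [r for r in self.chain_roles.values() if r in HISTONE_ROLES]

    # -- basepair coordinate system ---------------------------------------
    @property
    def bp_indices(self) -> np.ndarray:
        """Valid basepair indices (bp 0 at the pseudo-dyad)."""
        return np.arange(self.n_basepairs) - self.dyad_bp_offset

    def bp_to_strand_positions(self, bp: int) -> tuple[int, int]:
        """Map a basepair index to (strand-I position, strand-J position)."""
        i = self.dyad_bp_offset + bp
        if not 0 <= i < self.n_basepairs:
            raise SelectionError(
                f"basepair {bp} outside valid range "
                f"[{-self.dyad_bp_offset}, {self.n_basepairs - 1 - self.dyad_bp_offset}]")
        return i, self.n_basepairs - 1 - i

    def shl(self, bp: int) -> float:
        """Superhelix location, a derived label only (~10 bp per turn)."""
        return bp / 10.0

    def to_json(self) -> str:
        payload = {
            "chain_roles": self.chain_roles,
            "named_regions": {k: [v[0], list(v[1])] for k, v in self.named_regions.items()},
            "dimers": {k: list(v) for k, v in self.dimers.items()},
            "n_basepairs": self.n_basepairs,
            "dyad_bp_offset": self.dyad_bp_offset,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SiteSelection:
    """Atom indices organised into analysis groups (sites)."""

    label: str
    groups: list[np.ndarray]
    site_labels: list[str]
    grouping: str  # "residue" | "basepair" | "pooled"

    def __post_init__(self) -> None:
        for g in self.groups:
            if len(g) == 0:
                raise SelectionError(f"empty group in selection {self.label!r}")
        if len(self.groups) != len(self.site_labels):
            raise ValueError("one label per group required")

    @property
    def n_sites(self) -> int:
        return len(self.groups)

    @property
    def atom_indices(self) -> np.ndarray:
        """Unique, sorted union of all group indices."""
        return np.unique(np.concatenate(self.groups))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_pdb_atoms(path: str):
    """Parse ATOM/HETATM records of (possibly multi-model) PDB text.

    Keeps altloc '' / 'A' only. Returns per-atom identity arrays and a list
    of coordinate frames (one per MODEL; a model-less file yields one frame).
    """
    names: list[str] = []
    elements: list[str] = []
    resnums: list[int] = []
    resnames: list[str] = []
    chains: list[str] = []
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    in_model = False
    first_model_done = False
    try:
        fh = open(path)
    except OSError as exc:
        raise InputError(f"cannot open {path}: {exc}") from exc
    with fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    frames.append(current)
                    first_model_done = True
                    current = []
                in_model = True
            elif rec == "ENDMDL":
                frames.append(current)
                first_model_done = True
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                altloc = line[16]
                if altloc not in (" ", "A"):
                    continue
                if line[17:20].strip() in _SKIP_RESNAMES:
                    continue
                try:
                    x = float(line[30:38])
                    y = float(line[38:46])
                    z = float(line[46:54])
                except ValueError as exc:
                    raise InputError(
                        f"{path}:{lineno}: unparseable coordinates") from exc
                current.append((x, y, z))
                if not first_model_done:
                    name = line[12:16].strip()
                    element_field = line[76:78] if len(line) >= 78 else ""
                    try:
                        el = infer_element(name, element_field)
                    except InputError as exc:
                        raise InputError(
                            f"{path}:{lineno}: {exc} (atom {name!r})") from exc
                    names.append(name)
                    elements.append(el)
                    try:
                        resnums.append(int(line[22:26]))
                    except ValueError as exc:
                        raise InputError(
                            f"{path}:{lineno}: unparseable residue number") from exc
                    resnames.append(line[17:20].strip())
                    chains.append(line[21].strip() or "A")
    if current:
        frames.append(current)
    if not frames or not frames[0]:
        raise InputError(f"{path}: no ATOM/HETATM coordinates found")
    _ = in_model
    return names, elements, resnums, resnames, chains, [
        np.asarray(f, dtype=float) for f in frames if f]


def read_structure(path: str) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    Multi-model files expose model 1 as the reference coordinate set. Masses
    come from the standard atomic-weight table; an unresolvable element is an
    error naming the offending atom.
    """
    names, elements, resnums, resnames, chains, frames = _parse_pdb_atoms(path)
    masses = []
    for nm, el in zip(names, elements):
        if el not in ATOMIC_MASSES:
            raise InputError(f"unknown element {el!r} for atom {nm!r}")
        masses.append(ATOMIC_MASSES[el])
    return MolecularSystem(
        atom_names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        residue_numbers=np.asarray(resnums, dtype=int),
        residue_names=np.asarray(resnames, dtype=object),
        chain_ids=np.asarray(chains, dtype=object),
        masses=np.asarray(masses, dtype=float),
        reference_coords=frames[0],
    )


def read_trajectory(system: MolecularSystem, path: str,
                    window_fraction: float | None = None,
                    dt_ns: float = 1.0) -> TrajectorySegment:
    """Read a coordinate trajectory matching ``system``.

    Multi-model PDB files are parsed directly; any other format (XTC, DCD,
    TRR, ...) is delegated to MDAnalysis. Frame times default to the frame
    index times ``dt_ns`` when the file carries no time information.
    ``window_fraction`` restricts the analysis window to the final fraction
    of frames (mirroring equilibrated-tail harvesting); default is the whole
    trajectory.
    """
    if str(path).lower().endswith((".pdb", ".ent")):
        *_ids, frames = _parse_pdb_atoms(str(path))
        coords = np.stack(frames)
        times = np.arange(coords.shape[0], dtype=float) * dt_ns
    else:
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(system.n_atoms, trajectory=True)
            try:
                u.load_new(str(path))
            except (OSError, ValueError) as exc:
                raise InputError(f"cannot read trajectory {path}: {exc}") from exc
            coords = np.stack([u.atoms.positions.astype(float).copy()
                               for _ in u.trajectory])
            times = np.asarray(
                [ts.time for ts in u.trajectory], dtype=float) / 1000.0  # ps -> ns
        if coords.shape[0] == 0:
            raise InputError(f"{path}: empty trajectory")
        if np.any(np.diff(times) <= 0):
            times = np.arange(coords.shape[0], dtype=float) * dt_ns
    if coords.shape[1] != system.n_atoms:
        raise TopologyError(
            f"trajectory has {coords.shape[1]} atoms but topology has "
            f"{system.n_atoms}")
    window = (0, coords.shape[0])
    if window_fraction is not None:
        window = window_from_fraction(coords.shape[0], window_fraction)
    return TrajectorySegment(coords=coords, times=times, window=window)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def annotate_nucleosome(system: MolecularSystem,
                        config: dict) -> NucleosomeAnnotation:
    """Build a :class:`NucleosomeAnnotation` from a role-map config.

    ``config`` keys: ``chain_roles`` (chain -> role, required), ``regions``
    (name -> [role, start, end], optional), ``dyad_bp_offset`` (optional,
    default: centre of strand I), ``use_region_presets`` (default True).
    """
    chain_roles = dict(config["chain_roles"])
    for chain in chain_roles:
        if chain not in set(map(str, system.chain_ids)):
            raise InputError(f"config names absent chain {chain!r}")

    roles = set(chain_roles.values())
    n_bp = 0
    dyad = 0
    if ("DNA-I" in roles) != ("DNA-J" in roles):
        raise InputError("both DNA strands (DNA-I and DNA-J) must be annotated")
    if "DNA-I" in roles:
        ann_tmp = {c: r for c, r in chain_roles.items()}
        chain_i = next(c for c, r in ann_tmp.items() if r == "DNA-I")
        chain_j = next(c for c, r in ann_tmp.items() if r == "DNA-J")
        len_i = len(system.chain_residues(chain_i))
        len_j = len(system.chain_residues(chain_j))
        if len_i != len_j:
            raise InputError(
                f"DNA strands have unequal residue counts ({len_i} vs {len_j})")
        n_bp = len_i
        dyad = int(config.get("dyad_bp_offset", (n_bp - 1) // 2))
        if not 0 <= dyad < n_bp:
            raise InputError(f"dyad_bp_offset {dyad} outside strand (0..{n_bp - 1})")

    regions: dict[str, tuple[str, tuple[int, int]]] = {}
    candidates: list[tuple[str, str, int, int, bool]] = []
    if config.get("use_region_presets", True):
        for name, (role, (lo, hi)) in REGION_PRESETS.items():
            candidates.append((name, role, lo, hi, True))
    for name, spec in (config.get("regions") or {}).items():
        role, lo, hi = spec[0], int(spec[1]), int(spec[2])
        candidates.append((name, role, lo, hi, False))
    for name, role, lo, hi, preset in candidates:
        if role not in roles:
            if preset:
                continue
            raise InputError(f"region {name!r} references unannotated role {role!r}")
        chain = next(c for c, r in chain_roles.items() if r == role)
        present = set(system.chain_residues(chain))
        covered = set(range(lo, hi + 1)) <= present
        if not covered:
            if preset:
                continue
            raise InputError(
                f"region {name!r} ({lo}-{hi}) outside chain {chain!r} residues")
        regions[name] = (role, (lo, hi))

    dimers: dict[str, tuple[str, str]] = {}
    for label, (r1, r2) in {
        "homodimer-1": ("H3-like", "H4"),
        "homodimer-2": ("H3-like'", "H4'"),
        "hetdimer-1": ("H2A", "H2B"),
        "hetdimer-2": ("H2A'", "H2B'"),
    }.items():
        if r1 in roles and r2 in roles:
            dimers[label] = (r1, r2)

    return NucleosomeAnnotation(
        chain_roles=chain_roles, named_regions=regions, dimers=dimers,
        n_basepairs=n_bp, dyad_bp_offset=dyad)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _class_mask(system: MolecularSystem, atom_class: str) -> np.ndarray:
    if atom_class in ("CA", "Ca", "calpha"):
        return (system.atom_names == "CA") & (system.elements == "C")
    if atom_class == "heavy":
        return system.heavy_mask()
    if atom_class == "all":
        return np.ones(system.n_atoms, dtype=bool)
    if atom_class == "phosphate":
        return system.atom_names == "P"
    raise SelectionError(f"unknown atom class {atom_class!r}")


def select_sites(system: MolecularSystem,
                 annotation: NucleosomeAnnotation,
                 role: str | None = None,
                 region: str | None = None,
                 residues: list[int] | None = None,
                 bp: list[int] | None = None,
                 atom_class: str = "CA",
                 pooled: bool = False) -> SiteSelection:
    """Resolve a role/region/basepair query to grouped atom indices.

    Protein queries group per residue; ``atom_class='basepair'`` groups the
    heavy atoms of both paired nucleotides per basepair. ``pooled`` collapses
    everything into a single group.
    """
    if atom_class == "basepair":
        if not annotation.has_dna:
            raise SelectionError("basepair query requires both DNA strands annotated")
        chain_i = annotation.role_chain("DNA-I")
        chain_j = annotation.role_chain("DNA-J")
        res_i = system.chain_residues(chain_i)
        res_j = system.chain_residues(chain_j)
        heavy = system.heavy_mask()
        bps = list(bp) if bp is not None else list(annotation.bp_indices)
        groups, labels = [], []
        for b in bps:
            pi, pj = annotation.bp_to_strand_positions(int(b))
            gi = system.residue_atoms(chain_i, res_i[pi])
            gj = system.residue_atoms(chain_j, res_j[pj])
            g = np.concatenate([gi, gj])
            g = g[heavy[g]]
            if g.size == 0:
                raise SelectionError(f"basepair {b}: no heavy atoms")
            groups.append(np.sort(g))
            labels.append(f"bp{int(b):+d}")
        label = f"basepairs[{bps[0]}..{bps[-1]}]"
        if pooled:
            groups = [np.unique(np.concatenate(groups))]
            labels = [label]
        return SiteSelection(label=label, groups=groups, site_labels=labels,
                             grouping="pooled" if pooled else "basepair")

    if region is not None:
        if region not in annotation.named_regions:
            raise SelectionError(f"unknown region {region!r}")
        role, (lo, hi) = annotation.named_regions[region]
        residues = [r for r in range(lo, hi + 1)]
    if role is None:
        raise SelectionError("query must name a role, region, or basepair range")
    chain = annotation.role_chain(role)
    all_res = system.chain_residues(chain)
    use_res = [r for r in (residues if residues is not None else all_res)]
    missing = [r for r in use_res if r not in set(all_res)]
    if missing:
        raise SelectionError(f"residues {missing} not present in chain {chain!r}")
    mask = _class_mask(system, atom_class)
    groups, labels = [], []
    for r in use_res:
        g = system.residue_atoms(chain, r)
        g = g[mask[g]]
        if g.size == 0:
            continue
        groups.append(np.sort(g))
        labels.append(f"{chain}:{r}")
    if not groups:
        raise SelectionError(
            f"query (role={role!r}, region={region!r}, class={atom_class!r}) "
            "selected no atoms")
    label = region or role
    if pooled:
        groups = [np.unique(np.concatenate(groups))]
        labels = [label]
    return SiteSelection(label=label, groups=groups, site_labels=labels,
                         grouping="pooled" if pooled else "residue")


# ---------------------------------------------------------------------------
# writers & config
# ---------------------------------------------------------------------------

def write_pdb(system: MolecularSystem, path: str,
              coords: np.ndarray | None = None,
              frames: np.ndarray | None = None) -> None:
    """Write a (multi-model) PDB file.

    ``coords`` overrides the reference coordinates; ``frames`` with shape
    (n_frames, n_atoms, 3) produces a multi-model file.
    """
    def _atom_line(i: int, xyz: np.ndarray) -> str:
        name = str(system.atom_names[i])
        # PDB name column convention: 1-char elements start in column 14
        nm = f" {name:<3s}" if len(name) < 4 and len(str(system.elements[i])) == 1 else f"{name:<4s}"
        return (f"ATOM  {min(i + 1, 99999):5d} {nm}{'':1s}"
                f"{str(system.residue_names[i])[:3]:>3s} "
                f"{str(system.chain_ids[i])[:1]:1s}"
                f"{int(system.residue_numbers[i]):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          "
                f"{str(system.elements[i]):>2s}\n")

    with open(path, "w") as fh:
        if frames is not None:
            for m, frame in enumerate(frames, start=1):
                fh.write(f"MODEL     {m:4d}\n")
                for i in range(system.n_atoms):
                    fh.write(_atom_line(i, frame[i]))
                fh.write("ENDMDL\n")
        else:
            xyz = system.reference_coords if coords is None else np.asarray(coords)
            for i in range(system.n_atoms):
                fh.write(_atom_line(i, xyz[i]))
        fh.write("END\n")


def write_selection_tsv(system: MolecularSystem, selection: SiteSelection,
                        path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chain\tresnum\tatomname\tgroup\n")
        for g, lab in zip(selection.groups, selection.site_labels):
            for a in g:
                fh.write(f"{system.chain_ids[a]}\t{system.residue_numbers[a]}\t"
                         f"{system.atom_names[a]}\t{lab}\n")


def load_config(path: str) -> dict:
    """Load a TOML or JSON config file (by extension)."""
    p = str(path)
    if p.endswith(".toml"):
        import tomllib
        with open(p, "rb") as fh:
            return tomllib.load(fh)
    with open(p) as fh:
        return json.load(fh)
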