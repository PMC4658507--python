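"""Crystal-structure comparison utilities.

Sequence-guided residue correspondence between two structures, matched-residue
C-alpha RMSD after least-squares superposition, basepair counting, and
insertion detection between homologous chains. These back the crystal-level
sanity checks that only need two deposited nucleosome structures.
"""

from __future__ import annotations

import numpy as np

from .core import (MolecularSystem, NucleosomeAnnotation, SelectionError)
from .geometry import kabsch_superpose

__all__ = [
    "chain_sequence", "align_residue_pairs", "matched_ca_rmsd",
    "count_basepairs", "insertion_in_region", "NUCLEOSOME_CHAIN_ROLES",
]

# chain layout shared by the classic octameric nucleosome depositions:
# four histone pairs A-H, DNA strands I and J
NUCLEOSOME_CHAIN_ROLES = {
    "A": "H3-like", "B": "H4", "C": "H2A", "D": "H2B",
    "E": "H3-like'", "F": "H4'", "G": "H2A'", "H": "H2B'",
    "I": "DNA-I", "J": "DNA-J",
}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "HSD": "H", "HSE": "H", "HSP": "H",
}


def chain_sequence(system: MolecularSystem, chain: str
                   ) -> tuple[str, list[int]]:
    """One-letter sequence of a protein chain plus parallel residue numbers."""
    seq, nums = [], []
    for resnum in system.chain_residues(chain):
        atoms = system.residue_atoms(chain, resnum)
        resname = str(system.residue_names[atoms[0]])
        if resname in _THREE_TO_ONE:
            seq.append(_THREE_TO_ONE[resname])
            nums.append(resnum)
    if not seq:
        raise SelectionError(f"chain {chain!r} has no standard protein residues")
    return "".join(seq), nums


def _global_alignment(seq_a: str, seq_b: str):
    from Bio import Align
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0  # free end gaps (semi-global)
    return aligner.align(seq_a, seq_b)[0]


def align_residue_pairs(system_a: MolecularSystem, chain_a: str,
                        system_b: MolecularSystem, chain_b: str,
                        identical_only: bool = False
                        ) -> list[tuple[int, int]]:
    """Residue-number pairs matched by global sequence alignment."""
    seq_a, nums_a = chain_sequence(system_a, chain_a)
    seq_b, nums_b = chain_sequence(system_b, chain_b)
    aln = _global_alignment(seq_a, seq_b)
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            ia, ib = a0 + k, b0 + k
            if identical_only and seq_a[ia] != seq_b[ib]:
                continue
            pairs.append((nums_a[ia], nums_b[ib]))
    return pairs


def _ca_coord(system: MolecularSystem, chain: str, resnum: int
              ) -> np.ndarray | None:
    atoms = system.residue_atoms(chain, resnum)
    hit = atoms[(system.atom_names[atoms] == "CA")
                & (system.elements[atoms] == "C")]
    return system.reference_coords[hit[0]] if hit.size else None


def matched_ca_rmsd(system_a: MolecularSystem, system_b: MolecularSystem,
                    chain_pairs: list[tuple[str, str]],
                    residue_ranges: dict[str, tuple[int, int]] | None = None
                    ) -> tuple[float, int]:
    """C-alpha RMSD of B superposed onto A over sequence-matched residues.

    ``chain_pairs`` lists (chain in A, chain in B); ``residue_ranges``
    optionally restricts each A-chain to an inclusive residue window (e.g. the
    histone fold). Returns (rmsd in Angstrom, number of matched CA pairs).
    """
    xa, xb = [], []
    for ca, cb in chain_pairs:
        rng = residue_ranges.get(ca) if residue_ranges else None
        for ra, rb in align_residue_pairs(system_a, ca, system_b, cb):
            if rng and not rng[0] <= ra <= rng[1]:
                continue
            pa = _ca_coord(system_a, ca, ra)
            pb = _ca_coord(system_b, cb, rb)
            if pa is not None and pb is not None:
                xa.append(pa)
                xb.append(pb)
    if len(xa) < 3:
        raise SelectionError("fewer than 3 matched CA pairs")
    sup = kabsch_superpose(np.asarray(xb), np.asarray(xa))
    return sup.rmsd, len(xa)


def count_basepairs(system: MolecularSystem,
                    annotation: NucleosomeAnnotation) -> int:
    """Paired basepairs via the annotation's strand-pairing bijection."""
    n = 0
    for b in annotation.bp_indices:
        pi, pj = annotation.bp_to_strand_positions(int(b))
        if 0 <= pi < annotation.n_basepairs and 0 <= pj < annotation.n_basepairs:
            n += 1
    return n


def insertion_in_region(system_ref: MolecularSystem, chain_ref: str,
                        system_var: MolecularSystem, chain_var: str,
                        region: tuple[int, int]) -> int:
    """Net insertion length in the variant chain within a reference region.

    Counts alignment columns where the variant has a residue and the
    reference a gap, between the reference residues bounding ``region``
    (inclusive residue numbers of the reference chain).
    """
    seq_r, nums_r = chain_sequence(system_ref, chain_ref)
    seq_v, nums_v = chain_sequence(system_var, chain_var)
    aln = _global_alignment(seq_r, seq_v)
    # expand to per-column (ref index or None, var index or None)
    cols: list[tuple[int | None, int | None]] = []
    blocks = list(zip(*aln.aligned))
    prev_a = prev_b = 0
    for (a0, a1), (b0, b1) in blocks:
        gap_a = a0 - prev_a
        gap_b = b0 - prev_b
        for k in range(gap_a):
            cols.append((prev_a + k, None))
        for k in range(gap_b):
            cols.append((None, prev_b + k))
        for k in range(a1 - a0):
            cols.append((a0 + k, b0 + k))
        prev_a, prev_b = a1, b1
    for k in range(len(seq_r) - prev_a):
        cols.append((prev_a + k, None))
    for k in range(len(seq_v) - prev_b):
        cols.append((None, prev_b + k))

    lo, hi = region
    inside = False
    insertions = 0
    for ia, ib in cols:
        if ia is not None:
            resnum = nums_r[ia]
            inside = lo <= resnum <= hi
        elif inside and ib is not None:
            insertions += 1
    return insertions
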