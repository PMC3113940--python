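"""Parsing of protein structures and computation of per-residue descriptors.

Every downstream stage (potential derivation, ΔΔG prediction, optimality
scoring) consumes the four descriptors computed here for each residue of a
parsed structure:

``s``
    amino-acid type, one of the 20 standard residues;
``t``
    discrete backbone torsion domain (seven-state Ramachandran partition,
    :data:`stabscan.constants.TORSION_DOMAINS`);
``a``
    relative solvent accessibility in percent, Shrake-Rupley SASA divided
    by the Gly-X-Gly reference area of the residue type;
``d``
    for residue pairs, the distance between side-chain geometric centres.

Only standard amino acids with resolved N, Cα and C backbone atoms are
retained; heteroatoms, waters and incomplete residues are dropped before
any descriptor (including accessibility) is computed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.vectors import calc_dihedral

from . import constants as C

__all__ = [
    "Residue",
    "ProteinStructure",
    "StructureParseError",
    "EmptyStructureError",
    "parse_structure",
    "load_structure",
    "compute_accessibility",
    "assign_torsion_domains",
    "pairwise_centroid_distances",
    "classify_core_surface",
    "descriptor_table",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}
#: maximum C(i)-N(i+1) distance accepted as a peptide bond (Å)
_PEPTIDE_BOND_MAX = 1.9


class StructureParseError(ValueError):
    """The input could not be parsed as a PDB structure."""


class EmptyStructureError(StructureParseError):
    """Parsing succeeded but no usable residue remained."""


@dataclass
class Residue:
    """One standard residue with its descriptors.

    ``seq_number`` keeps the author numbering (plus insertion code) verbatim
    so that mutation lists expressed in PDB numbering resolve correctly;
    ``index`` is the stable 0-based position used internally.
    """

    index: int
    chain: str
    resseq: int
    icode: str
    aa: str                      # one-letter code
    centroid: np.ndarray         # side-chain geometric centre (Cα fallback)
    phi: float | None = None     # degrees
    psi: float | None = None
    t_label: str = C.TORSION_UNDEFINED
    a: float = float("nan")      # relative accessibility, percent

    @property
    def s(self) -> int:
        return C.AA_INDEX[self.aa]

    @property
    def t(self) -> int | None:
        """Torsion-domain state index, or None when undefined."""
        return C.TORSION_INDEX.get(self.t_label)

    @property
    def seq_number(self) -> str:
        return f"{self.resseq}{self.icode}".strip()

    @property
    def is_core(self) -> bool:
        return self.a < C.CORE_SURFACE_THRESHOLD


@dataclass
class ProteinStructure:
    """A parsed structure with descriptors and the recorded pair distances."""

    id: str
    residues: list[Residue]
    pairs: dict[tuple[int, int], float] = field(default_factory=dict)
    distance_cutoff: float = C.DEFAULT_DISTANCE_CUTOFF

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        """Recorded distance partners of residue ``i`` as (index, d) pairs."""
        out = []
        for (p, q), d in self.pairs.items():
            if p == i:
                out.append((q, d))
            elif q == i:
                out.append((p, d))
        return out

    def neighbor_lists(self) -> list[list[tuple[int, float]]]:
        """Partner lists for all residues (index aligned with residues)."""
        lists: list[list[tuple[int, float]]] = [[] for _ in self.residues]
        for (p, q), d in self.pairs.items():
            lists[p].append((q, d))
            lists[q].append((p, d))
        return lists

    def find(self, chain: str, seq_number: str) -> Residue:
        """Resolve an author-numbered position (e.g. ``'52'`` or ``'52A'``)."""
        for r in self.residues:
            if r.chain == chain and r.seq_number == str(seq_number):
                return r
        raise KeyError(f"no residue {seq_number!r} in chain {chain!r} of {self.id}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_structure(
    source: str | Path | io.TextIOBase,
    chain_filter: Sequence[str] | None = None,
    structure_id: str | None = None,
) -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    ``source`` may be a filesystem path, an open text handle, or a string
    containing raw PDB records.  Only MODEL 1 of multi-model files is read;
    alternate locations resolve to the highest-occupancy conformer; HETATM
    records and waters are ignored.  Residues lacking any of N, Cα, C are
    excluded.  Descriptors are *not* computed here; use
    :func:`load_structure` for the full pipeline.
    """
    handle: io.TextIOBase
    name = structure_id or "structure"
    if isinstance(source, io.TextIOBase):
        handle = source
    elif isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        path = Path(source)
        if structure_id is None:
            name = path.stem
        try:
            handle = open(path)
        except OSError as exc:
            raise StructureParseError(f"cannot read {path}: {exc}") from exc
    else:
        handle = io.StringIO(source)

    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(name, handle)
    except Exception as exc:  # Bio.PDB raises its own exception types
        raise StructureParseError(f"PDB parse failure: {exc}") from exc
    finally:
        if handle is not source:
            handle.close()

    if len(bio) == 0:
        raise EmptyStructureError("no model found in input")
    model = next(iter(bio))

    # Drop everything the descriptor pipeline must not see, so that the
    # retained atoms alone define solvent occlusion.
    for bio_chain in list(model):
        if chain_filter is not None and bio_chain.id not in chain_filter:
            model.detach_child(bio_chain.id)
            continue
        for res in list(bio_chain):
            hetflag, _, _ = res.id
            keep = (
                hetflag == " "
                and res.get_resname() in C.THREE_TO_ONE
                and all(res.has_id(atom) for atom in ("N", "CA", "C"))
            )
            if not keep:
                bio_chain.detach_child(res.id)
        if len(bio_chain) == 0:
            model.detach_child(bio_chain.id)

    residues: list[Residue] = []
    bio_residues = []
    for bio_chain in model:
        for res in bio_chain:
            _, resseq, icode = res.id
            side = [a for a in res.get_atoms() if a.get_name() not in _BACKBONE
                    and a.element != "H"]
            if side:
                centroid = np.mean([a.coord for a in side], axis=0)
            else:
                centroid = np.array(res["CA"].coord, dtype=float)
            residues.append(Residue(
                index=len(residues),
                chain=bio_chain.id,
                resseq=resseq,
                icode=icode.strip(),
                aa=C.THREE_TO_ONE[res.get_resname()],
                centroid=np.asarray(centroid, dtype=float),
            ))
            bio_residues.append(res)

    if not residues:
        raise EmptyStructureError(f"no usable protein residue in {name!r}")

    structure = ProteinStructure(id=name, residues=residues)
    structure._bio_model = model          # kept for SASA / torsion passes
    structure._bio_residues = bio_residues
    return structure


def load_structure(
    source: str | Path | io.TextIOBase,
    chain_filter: Sequence[str] | None = None,
    structure_id: str | None = None,
    distance_cutoff: float = C.DEFAULT_DISTANCE_CUTOFF,
    n_points: int = C.SASA_N_POINTS,
) -> ProteinStructure:
    """Parse a structure and compute all residue descriptors and pair distances."""
    s = parse_structure(source, chain_filter=chain_filter, structure_id=structure_id)
    compute_accessibility(s, n_points=n_points)
    assign_torsion_domains(s)
    pairwise_centroid_distances(s, cutoff=distance_cutoff)
    return s


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------

def compute_accessibility(
    structure: ProteinStructure,
    probe_radius: float = C.SASA_PROBE_RADIUS,
    n_points: int = C.SASA_N_POINTS,
) -> np.ndarray:
    """Relative solvent accessibility (percent) for every residue, in place.

    Absolute per-residue SASA is computed with the Shrake-Rupley sphere
    quadrature (probe 1.4 Å, 960 points per atom by default) over the
    retained protein atoms only, then normalized by the Gly-X-Gly reference
    area of the residue type and clipped to [0, 100].
    """
    model = getattr(structure, "_bio_model", None)
    if model is None:
        raise ValueError("structure was not produced by parse_structure")
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(model, level="R")
    values = np.empty(len(structure))
    for r, bio_res in zip(structure.residues, structure._bio_residues):
        rel = 100.0 * bio_res.sasa / C.GXG_REFERENCE_SASA[r.aa]
        r.a = float(np.clip(rel, 0.0, 100.0))
        values[r.index] = r.a
    return values


def assign_torsion_domains(structure: ProteinStructure) -> list[str]:
    """Backbone (φ, ψ) dihedrals and torsion-domain labels, in place.

    φ of residue i needs C(i-1); ψ needs N(i+1); both require an actual
    peptide bond (C-N distance below 1.9 Å) between consecutive retained
    residues of the same chain.  Chain termini and chain breaks are labelled
    ``undefined`` and never raise.
    """
    labels: list[str] = []
    bio = structure._bio_residues
    res = structure.residues
    for i, r in enumerate(res):
        prev_res = bio[i - 1] if i > 0 and res[i - 1].chain == r.chain else None
        next_res = (bio[i + 1] if i + 1 < len(res) and res[i + 1].chain == r.chain
                    else None)
        phi = psi = None
        this = bio[i]
        if prev_res is not None and _bonded(prev_res["C"], this["N"]):
            phi = math.degrees(calc_dihedral(
                prev_res["C"].get_vector(), this["N"].get_vector(),
                this["CA"].get_vector(), this["C"].get_vector()))
        if next_res is not None and _bonded(this["C"], next_res["N"]):
            psi = math.degrees(calc_dihedral(
                this["N"].get_vector(), this["CA"].get_vector(),
                this["C"].get_vector(), next_res["N"].get_vector()))
        r.phi, r.psi = phi, psi
        r.t_label = C.torsion_domain(phi, psi)
        labels.append(r.t_label)
    return labels


def _bonded(c_atom, n_atom) -> bool:
    return float(np.linalg.norm(c_atom.coord - n_atom.coord)) < _PEPTIDE_BOND_MAX


def pairwise_centroid_distances(
    structure: ProteinStructure,
    cutoff: float = C.DEFAULT_DISTANCE_CUTOFF,
) -> dict[tuple[int, int], float]:
    """Record all residue pairs with centroid distance ≤ ``cutoff``, in place.

    Pairs separated by fewer than :data:`~stabscan.constants.MIN_SEQUENCE_SEPARATION`
    positions along the same chain are excluded; pairs across chains always
    qualify.  Keys are (i, j) with i < j on the internal 0-based index.
    """
    from scipy.spatial import cKDTree

    coords = np.array([r.centroid for r in structure.residues])
    pairs: dict[tuple[int, int], float] = {}
    if len(coords) >= 2:
        tree = cKDTree(coords)
        for i, j in sorted(tree.query_pairs(cutoff)):
            ri, rj = structure.residues[i], structure.residues[j]
            if ri.chain == rj.chain and abs(j - i) < C.MIN_SEQUENCE_SEPARATION:
                continue
            pairs[(i, j)] = float(np.linalg.norm(coords[i] - coords[j]))
    structure.pairs = pairs
    structure.distance_cutoff = cutoff
    return pairs


def classify_core_surface(
    structure: ProteinStructure,
    threshold: float = C.CORE_SURFACE_THRESHOLD,
) -> list[str]:
    """Per-residue burial class: ``core`` if a < threshold, else ``surface``.

    The boundary value (a == threshold) is surface, matching a strict
    "smaller than" reading of the core definition.
    """
    out = []
    for r in structure.residues:
        if math.isnan(r.a):
            out.append("unclassified")
        else:
            out.append("core" if r.a < threshold else "surface")
    return out


def descriptor_table(structure: ProteinStructure):
    """Per-residue descriptors as a :class:`pandas.DataFrame`."""
    import pandas as pd

    cls = classify_core_surface(structure)
    return pd.DataFrame({
        "chain": [r.chain for r in structure.residues],
        "seq_number": [r.seq_number for r in structure.residues],
        "aa": [r.aa for r in structure.residues],
        "torsion": [r.t_label for r in structure.residues],
        "accessibility": [r.a for r in structure.residues],
        "burial": cls,
    })


def write_descriptor_table(structure: ProteinStructure, path: str | Path) -> None:
    descriptor_table(structure).to_csv(path, sep="\t", index=False, float_format="%.2f")
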