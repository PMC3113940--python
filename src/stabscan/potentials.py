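"""Knowledge-based statistical potentials over residue descriptors.

Thirteen energy terms are derived from a collection of structures by an
inverse-Boltzmann transform of descriptor frequencies.  Each term couples
two or three *descriptor groups*; a group is one descriptor or a composite
of descriptors of the same residue.  The descriptors are the amino-acid
type ``s`` (20 states), the backbone torsion domain ``t`` (7 states), the
binned relative solvent accessibility ``a``, and, for residue pairs, the
binned side-chain centroid distance ``d``.

For a two-group coupling the energy of the joint state (v, w) is

    W(v, w) = -kT ln [ P(v, w) / (P(v) P(w)) ]

and for a three-group coupling the residual three-way coupling beyond all
pairwise ones,

    W(v, w, x) = -kT ln [ P(v,w,x) P(v) P(w) P(x) / (P(v,w) P(v,x) P(w,x)) ]

with all probabilities estimated from smoothed counts (a constant
pseudocount added to every joint cell; marginals derive from the smoothed
joint, so exactly uniform counts give identically zero energies).

The mutation-level quantity ΔΔW used by the predictor is the difference in
total energy when the amino-acid type at one position is substituted with
all structural descriptors (t, a, d and all partners) held at their
wild-type values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import constants as C
from .structure import ProteinStructure

__all__ = [
    "BinningScheme",
    "PotentialTable",
    "PotentialSet",
    "TERM_ORDER",
    "TERM_GROUPS",
    "count_frequencies",
    "derive_potentials",
    "delta_energy_terms",
    "total_energy",
]

# ---------------------------------------------------------------------------
# Term definitions
# ---------------------------------------------------------------------------

#: Fixed order of the 13 terms; the predictor's first 13 coefficients follow
#: this order.
TERM_ORDER: tuple[str, ...] = (
    "st", "as", "sd", "sds", "stt", "sst", "aas",
    "ass", "ast", "asd", "std", "asdas", "stdst",
)

#: Descriptor-group composition of every term.  Codes: ``si``/``ti``/``ai``
#: refer to the first residue of an (ordered) pair or to the residue itself
#: for single-residue terms, ``sj``/``tj``/``aj`` to the second residue,
#: ``d`` to the pair distance.  A tuple of several codes is a composite
#: group (its states are the Cartesian product).
TERM_GROUPS: dict[str, tuple[tuple[str, ...], ...]] = {
    # single-residue couplings
    "st":    (("si",), ("ti",)),
    "as":    (("ai",), ("si",)),
    "ast":   (("ai",), ("si",), ("ti",)),
    # pair couplings involving the distance descriptor
    "sd":    (("si",), ("d",)),
    "sds":   (("si",), ("d",), ("sj",)),
    "asd":   (("ai",), ("si",), ("d",)),
    "std":   (("si",), ("ti",), ("d",)),
    # pair couplings between descriptors of the two residues
    "stt":   (("si",), ("ti",), ("tj",)),
    "sst":   (("si",), ("sj",), ("tj",)),
    "aas":   (("ai",), ("aj",), ("sj",)),
    "ass":   (("ai",), ("si",), ("sj",)),
    # distance-coupled composite terms
    "asdas": (("ai", "si"), ("d",), ("aj", "sj")),
    "stdst": (("si", "ti"), ("d",), ("sj", "tj")),
}

#: Terms whose counting/evaluation loops run over ordered residue pairs.
PAIR_TERMS = frozenset(t for t, groups in TERM_GROUPS.items()
                       if any("d" in g or any(c.endswith("j") for c in g)
                              for g in groups))
RESIDUE_TERMS = tuple(t for t in TERM_ORDER if t not in PAIR_TERMS)


@dataclass(frozen=True)
class BinningScheme:
    """Discretization of the continuous descriptors.

    ``accessibility_edges`` are percent boundaries (first 0, last 100);
    ``distance_edges`` are Å boundaries whose first/last values act as
    lower/upper cutoffs — pairs outside the range are skipped.
    """

    accessibility_edges: tuple[float, ...] = (0.0, 5.0, 15.0, 30.0, 50.0, 100.0)
    distance_edges: tuple[float, ...] = tuple(np.arange(3.0, 8.0 + 0.25, 0.5))
    torsion_alphabet: tuple[str, ...] = C.TORSION_DOMAINS

    def __post_init__(self):
        for edges in (self.accessibility_edges, self.distance_edges):
            if list(edges) != sorted(set(edges)):
                raise ValueError("bin boundaries must be strictly increasing")

    @property
    def n_acc(self) -> int:
        return len(self.accessibility_edges) - 1

    @property
    def n_dist(self) -> int:
        return len(self.distance_edges) - 1

    @property
    def n_torsion(self) -> int:
        return len(self.torsion_alphabet)

    def acc_bin(self, a: float) -> int | None:
        """Bin index of a relative accessibility; None if a is NaN."""
        if np.isnan(a):
            return None
        edges = self.accessibility_edges
        i = int(np.searchsorted(edges, a, side="right")) - 1
        return int(np.clip(i, 0, self.n_acc - 1))

    def dist_bin(self, d: float) -> int | None:
        """Bin index of a pair distance; None if outside the cutoffs."""
        edges = self.distance_edges
        if d < edges[0] or d > edges[-1]:
            return None
        i = int(np.searchsorted(edges, d, side="right")) - 1
        return int(np.clip(i, 0, self.n_dist - 1))

    def size(self, code: str) -> int:
        base = code[0]
        if base == "s":
            return C.N_AA
        if base == "t":
            return self.n_torsion
        if base == "a":
            return self.n_acc
        if base == "d":
            return self.n_dist
        raise KeyError(code)

    def group_size(self, group: Sequence[str]) -> int:
        n = 1
        for code in group:
            n *= self.size(code)
        return n

    def term_shape(self, term: str) -> tuple[int, ...]:
        return tuple(self.group_size(g) for g in TERM_GROUPS[term])

    def to_dict(self) -> dict:
        return {
            "accessibility_edges": list(self.accessibility_edges),
            "distance_edges": list(self.distance_edges),
            "torsion_alphabet": list(self.torsion_alphabet),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(tuple(d["accessibility_edges"]), tuple(d["distance_edges"]),
                   tuple(d["torsion_alphabet"]))


# ---------------------------------------------------------------------------
# State extraction and indexing
# ---------------------------------------------------------------------------

def _residue_states(structure: ProteinStructure, scheme: BinningScheme):
    """(s, t, a-bin) integer states per residue; None marks undefined."""
    out = []
    for r in structure.residues:
        out.append({"s": r.s, "t": r.t, "a": scheme.acc_bin(r.a)})
    return out


def _group_index(group: Sequence[str], scheme: BinningScheme,
                 st_i: dict, st_j: dict | None, dbin: int | None,
                 s_override: tuple[str, int] | None = None) -> int | None:
    """Flat index of a composite group; None if any component is undefined.

    ``s_override`` = ('i'|'j', state) substitutes the amino-acid type of one
    side of the pair, which is how mutant energies are evaluated.
    """
    k = 0
    for code in group:
        base, side = code[0], code[-1]
        if base == "d":
            v = dbin
        else:
            st = st_i if side == "i" else st_j
            v = st[base]
            if base == "s" and s_override is not None and side == s_override[0]:
                v = s_override[1]
        if v is None:
            return None
        k = k * scheme.size(code) + v
    return k


def _term_index(term: str, scheme: BinningScheme, st_i, st_j=None, dbin=None,
                s_override=None) -> tuple[int, ...] | None:
    idx = []
    for group in TERM_GROUPS[term]:
        k = _group_index(group, scheme, st_i, st_j, dbin, s_override)
        if k is None:
            return None
        idx.append(k)
    return tuple(idx)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_frequencies(
    structures: Iterable[ProteinStructure],
    scheme: BinningScheme | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Accumulate raw descriptor-combination counts for all 13 terms.

    Single-residue terms gain one count per residue with all required
    descriptors defined; pair terms gain one count per *ordered* pair
    (i→j and j→i) whose distance falls inside the binning range.  Returns
    the count tensors and a tally of skipped residues/pairs per term.
    """
    scheme = scheme or BinningScheme()
    structures = list(structures)
    if not structures:
        raise ValueError("empty structure collection")

    counts = {t: np.zeros(scheme.term_shape(t)) for t in TERM_ORDER}
    skipped = {t: 0 for t in TERM_ORDER}

    for s in structures:
        states = _residue_states(s, scheme)
        for term in RESIDUE_TERMS:
            for st in states:
                idx = _term_index(term, scheme, st)
                if idx is None:
                    skipped[term] += 1
                else:
                    counts[term][idx] += 1.0
        ordered = []
        for (i, j), d in s.pairs.items():
            dbin = scheme.dist_bin(d)
            if dbin is None:
                for term in PAIR_TERMS:
                    skipped[term] += 2
                continue
            ordered.append((states[i], states[j], dbin))
            ordered.append((states[j], states[i], dbin))
        for term in PAIR_TERMS:
            tensor = counts[term]
            for st_i, st_j, dbin in ordered:
                idx = _term_index(term, scheme, st_i, st_j, dbin)
                if idx is None:
                    skipped[term] += 1
                else:
                    tensor[idx] += 1.0
    return counts, skipped


# ---------------------------------------------------------------------------
# Inverse-Boltzmann energies
# ---------------------------------------------------------------------------

@dataclass
class PotentialTable:
    """Energies (kcal/mol) and audit counts for one coupling term."""

    term_id: str
    energies: np.ndarray
    counts: np.ndarray
    kT: float
    pseudocount: float

    @property
    def groups(self) -> tuple[tuple[str, ...], ...]:
        return TERM_GROUPS[self.term_id]


def _coupling_energy(counts: np.ndarray, pseudocount: float, kT: float) -> np.ndarray:
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    smoothed = counts + pseudocount
    if np.any(smoothed <= 0):
        raise ValueError(
            "zero counts with zero pseudocount: energies would be infinite")
    logp = np.log(smoothed / smoothed.sum())
    nd = counts.ndim
    if nd == 2:
        lv = _log_marginal(smoothed, keep=(0,))
        lw = _log_marginal(smoothed, keep=(1,))
        return -kT * (logp - lv - lw)
    if nd == 3:
        lv = _log_marginal(smoothed, keep=(0,))
        lw = _log_marginal(smoothed, keep=(1,))
        lx = _log_marginal(smoothed, keep=(2,))
        lvw = _log_marginal(smoothed, keep=(0, 1))
        lvx = _log_marginal(smoothed, keep=(0, 2))
        lwx = _log_marginal(smoothed, keep=(1, 2))
        return -kT * (logp + lv + lw + lx - lvw - lvx - lwx)
    raise ValueError(f"unsupported tensor rank {nd}")


def _log_marginal(smoothed: np.ndarray, keep: tuple[int, ...]) -> np.ndarray:
    axes = tuple(i for i in range(smoothed.ndim) if i not in keep)
    marg = smoothed.sum(axis=axes, keepdims=True)
    return np.log(marg / smoothed.sum())


@dataclass
class PotentialSet:
    """The 13 derived tables plus the scheme and provenance needed to reuse them."""

    scheme: BinningScheme
    tables: dict[str, PotentialTable]
    kT: float = C.KT_KCAL_MOL
    pseudocount: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, term: str) -> PotentialTable:
        return self.tables[term]

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "format": "stabscan-potentials/1",
            "kT": self.kT,
            "pseudocount": self.pseudocount,
            "scheme": self.scheme.to_dict(),
            "provenance": self.provenance,
            "tables": {
                t: {
                    "energies": tab.energies.tolist(),
                    "counts": tab.counts.tolist(),
                } for t, tab in self.tables.items()
            },
        }
        return json.dumps(payload, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "PotentialSet":
        d = json.loads(text)
        if d.get("format") != "stabscan-potentials/1":
            raise ValueError("unrecognized potential archive format")
        scheme = BinningScheme.from_dict(d["scheme"])
        tables = {
            t: PotentialTable(
                term_id=t,
                energies=np.asarray(tab["energies"], dtype=float),
                counts=np.asarray(tab["counts"], dtype=float),
                kT=d["kT"],
                pseudocount=d["pseudocount"],
            ) for t, tab in d["tables"].items()
        }
        return cls(scheme=scheme, tables=tables, kT=d["kT"],
                   pseudocount=d["pseudocount"], provenance=d.get("provenance", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PotentialSet":
        return cls.from_json(Path(path).read_text())


def derive_potentials(
    structures: Iterable[ProteinStructure] | None = None,
    scheme: BinningScheme | None = None,
    pseudocount: float = 1.0,
    kT: float = C.KT_KCAL_MOL,
    counts: dict[str, np.ndarray] | None = None,
) -> PotentialSet:
    """Derive the 13 potential tables from structures (or precomputed counts)."""
    scheme = scheme or BinningScheme()
    provenance: dict = {}
    if counts is None:
        if structures is None:
            raise ValueError("either structures or counts must be given")
        structures = list(structures)
        counts, _ = count_frequencies(structures, scheme)
        h = hashlib.sha256("|".join(sorted(s.id for s in structures)).encode())
        provenance = {"n_structures": len(structures),
                      "structure_ids_sha256": h.hexdigest()}
    tables = {
        t: PotentialTable(term_id=t, counts=c,
                          energies=_coupling_energy(c, pseudocount, kT),
                          kT=kT, pseudocount=pseudocount)
        for t, c in counts.items()
    }
    return PotentialSet(scheme=scheme, tables=tables, kT=kT,
                        pseudocount=pseudocount, provenance=provenance)


# ---------------------------------------------------------------------------
# Mutation energetics
# ---------------------------------------------------------------------------

def delta_energy_terms(
    structure: ProteinStructure,
    position: int,
    s_w: str,
    s_m: str,
    potentials: PotentialSet,
) -> np.ndarray:
    """ΔΔW vector (13 terms, kcal/mol) for mutating ``position`` s_w → s_m.

    Structural descriptors (torsion, accessibility, distances, partners)
    stay at their wild-type values; only the amino-acid type changes.  Each
    component equals the full mutant-minus-wild-type rescoring difference
    of its term because contributions not involving the mutated position
    cancel exactly.
    """
    res = structure.residues[position]
    if res.aa != s_w:
        raise ValueError(
            f"wild-type mismatch at {res.chain}{res.seq_number}: "
            f"structure has {res.aa}, mutation names {s_w}")
    if s_m == s_w:
        raise ValueError("self-mutations are not defined")
    scheme = potentials.scheme
    states = _residue_states(structure, scheme)
    st_pos = states[position]
    sw_i, sm_i = C.AA_INDEX[s_w], C.AA_INDEX[s_m]

    out = np.zeros(len(TERM_ORDER))
    partners = [(j, scheme.dist_bin(d)) for j, d in structure.neighbors(position)]
    partners = [(j, db) for j, db in partners if db is not None]

    for k, term in enumerate(TERM_ORDER):
        tab = potentials[term]
        delta = 0.0
        if term in PAIR_TERMS:
            for j, dbin in partners:
                st_j = states[j]
                # orientation: mutated residue first
                delta += _energy_delta(tab, scheme, st_pos, st_j, dbin,
                                       "i", sw_i, sm_i)
                # orientation: mutated residue second
                delta += _energy_delta(tab, scheme, st_j, st_pos, dbin,
                                       "j", sw_i, sm_i)
        else:
            iw = _term_index(term, scheme, st_pos, s_override=("i", sw_i))
            im = _term_index(term, scheme, st_pos, s_override=("i", sm_i))
            if iw is not None and im is not None:
                delta = float(tab.energies[im] - tab.energies[iw])
        out[k] = delta
    return out


def _energy_delta(tab: PotentialTable, scheme: BinningScheme,
                  st_i, st_j, dbin, side: str, sw: int, sm: int) -> float:
    iw = _term_index(tab.term_id, scheme, st_i, st_j, dbin, (side, sw))
    im = _term_index(tab.term_id, scheme, st_i, st_j, dbin, (side, sm))
    if iw is None or im is None:
        return 0.0
    return float(tab.energies[im] - tab.energies[iw])


def total_energy(
    structure: ProteinStructure,
    potentials: PotentialSet,
    sequence: Sequence[int] | None = None,
) -> np.ndarray:
    """Total per-term energy of the whole structure (13-vector, kcal/mol).

    ``sequence`` optionally overrides the amino-acid state of every residue
    (integer indices into the 20-letter alphabet), which allows scoring a
    mutant sequence threaded onto the wild-type backbone.  Single-residue
    terms sum over residues; pair terms sum over both orientations of every
    recorded pair, mirroring the counting convention.
    """
    scheme = potentials.scheme
    states = _residue_states(structure, scheme)
    if sequence is not None:
        if len(sequence) != len(states):
            raise ValueError("sequence override length mismatch")
        for st, s_new in zip(states, sequence):
            st["s"] = int(s_new)

    out = np.zeros(len(TERM_ORDER))
    pair_items = [(states[i], states[j], scheme.dist_bin(d))
                  for (i, j), d in structure.pairs.items()]
    pair_items = [p for p in pair_items if p[2] is not None]
    for k, term in enumerate(TERM_ORDER):
        tab = potentials[term]
        total = 0.0
        if term in PAIR_TERMS:
            for st_i, st_j, dbin in pair_items:
                for a, b in ((st_i, st_j), (st_j, st_i)):
                    idx = _term_index(term, scheme, a, b, dbin)
                    if idx is not None:
                        total += float(tab.energies[idx])
        else:
            for st in states:
                idx = _term_index(term, scheme, st)
                if idx is not None:
                    total += float(tab.energies[idx])
        out[k] = total
    return out
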