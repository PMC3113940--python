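"""Deterministic toy structures and simulated mutant datasets.

Experimental ΔΔG compilations and the structure sets behind published
statistical potentials are not redistributable, so every stage of this
package is exercised against a fully self-contained synthetic world:

* :func:`make_toy_structure` builds ideal-geometry backbones (helix, sheet
  or mixed motifs, with small seeded jitter on φ/ψ) carrying one
  pseudo-centroid side-chain atom per residue, emitted as standard PDB
  text that round-trips through the structure parser;
* :func:`make_ground_truth` derives potentials from a set of such
  structures and pairs them with documented ground-truth sigmoid
  parameters, defining a known generating model;
* :func:`simulate_mutant_dataset` draws distinct mutations, scores them
  with the ground-truth model and adds Gaussian measurement noise, giving
  a training table whose ideal predictor is known exactly.

The generated ΔΔG distribution is majority-destabilizing with values in
roughly [−5, +5] kcal/mol, mirroring the shape of experimental mutant
compilations; records above the +5 kcal/mol training cutoff are excluded
at the source so the set passes :func:`stabscan.training.filter_dataset`
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import constants as C
from .potentials import BinningScheme, PotentialSet, derive_potentials
from .predictor import (ModelParameters, N_COEFFICIENTS, mutation_features)
from .structure import ProteinStructure, load_structure
from .training import MutantRecord, DDG_TRAINING_CUTOFF

__all__ = [
    "make_toy_structure",
    "default_truth_parameters",
    "GroundTruthModel",
    "make_ground_truth",
    "SimulatedDataset",
    "simulate_mutant_dataset",
    "make_demo",
]

# ideal backbone geometry (Engh-Huber-style means)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.8

_MOTIF_ANGLES = {"helix": (-57.0, -47.0), "sheet": (-135.0, 135.0)}
#: jitter applied to every φ/ψ: Gaussian sd (deg), clipped so motif residues
#: stay inside their torsion domain
_JITTER_SD, _JITTER_CLIP = 5.0, 12.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom D given A-B-C, |CD|, angle BCD and dihedral ABCD."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _centroid_offset(aa: str) -> float:
    """Distance of the pseudo side-chain atom from Cα, scaling with volume."""
    return 1.5 * (C.RESIDUE_VOLUME[aa] / C.RESIDUE_VOLUME["A"]) ** (1.0 / 3.0)


def make_toy_structure(n_residues: int, motif: str = "mixed", seed: int = 0,
                       chain_id: str = "A", sequence: str | None = None) -> str:
    """Generate PDB-format text for a toy chain with the requested motif.

    ``motif`` is ``helix``, ``sheet`` or ``mixed`` (alternating blocks of
    nine helical and seven extended residues).  The sequence is drawn
    uniformly over the 20 standard types unless given explicitly; glycine
    carries no side-chain atom, every other residue a single CB
    pseudo-centroid placed along the standard tetrahedral direction at a
    volume-dependent distance.  Output is byte-deterministic given the
    arguments.
    """
    if not 3 <= n_residues <= 500:
        raise ValueError("n_residues must be in [3, 500]")
    if motif not in ("helix", "sheet", "mixed"):
        raise ValueError(f"unknown motif {motif!r}")
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = rng.choice(list(C.AMINO_ACIDS), size=n_residues)
    else:
        if len(sequence) != n_residues:
            raise ValueError("sequence length must equal n_residues")
        if any(aa not in C.AA_INDEX for aa in sequence):
            raise ValueError("sequence must use one-letter standard codes")
        sequence = list(sequence)

    phis = np.empty(n_residues)
    psis = np.empty(n_residues)
    for i in range(n_residues):
        kind = motif if motif != "mixed" else ("helix" if (i // 9) % 2 == 0
                                               else "sheet")
        phi0, psi0 = _MOTIF_ANGLES[kind]
        jit = np.clip(rng.normal(0.0, _JITTER_SD, 2), -_JITTER_CLIP, _JITTER_CLIP)
        phis[i], psis[i] = phi0 + jit[0], psi0 + jit[1]

    # backbone chain growth
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = math.radians(180.0 - _A_N_CA_C)
    CCoord = [CA[0] + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])]
    O = []
    for i in range(n_residues):
        O.append(_place(N[i], CA[i], CCoord[i], _B_C_O, _A_CA_C_O,
                        psis[i] + 180.0))
        if i + 1 < n_residues:
            N.append(_place(N[i], CA[i], CCoord[i], _B_C_N, _A_CA_C_N, psis[i]))
            CA.append(_place(CA[i], CCoord[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0))
            CCoord.append(_place(CCoord[i], N[i + 1], CA[i + 1], _B_CA_C,
                                 _A_N_CA_C, phis[i + 1]))

    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        res3 = C.ONE_TO_THREE[aa]
        atoms = [("N", N[i]), ("CA", CA[i]), ("C", CCoord[i]), ("O", O[i])]
        if aa != "G":
            v1 = N[i] - CA[i]
            v2 = CCoord[i] - CA[i]
            v1, v2 = v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)
            bis = v1 + v2
            bis /= np.linalg.norm(bis)
            perp = np.cross(v1, v2)
            perp /= np.linalg.norm(perp)
            direction = -bis + 1.2 * perp
            direction /= np.linalg.norm(direction)
            atoms.append(("CB", CA[i] + _centroid_offset(aa) * direction))
        for name, xyz in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} {res3} {chain_id}{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {name[0]:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Ground-truth generating model
# ---------------------------------------------------------------------------

def default_truth_parameters() -> ModelParameters:
    """Documented ground-truth sigmoid parameters of the generating model.

    The energy-term weights contrast a buried-core and an exposed-surface
    regime (inflections between 15 and 45 % accessibility); four of the
    sixteen coefficients (aas, ast, std, stdst) are genuinely constant in
    A (f = 0), giving the parameter-reduction procedure real targets.  The
    volume coefficients are strongest in the core, and the independent
    term's positive offset skews the generated ΔΔG distribution toward
    destabilization.  Rows follow
    :data:`stabscan.predictor.COEFFICIENT_NAMES`; columns are (c, r, f, b).
    """
    theta = np.array([
        # c      r       f       b
        [20.0,  0.12,  -0.20,   0.40],   # st
        [30.0,  0.10,   0.25,   0.10],   # as
        [25.0, -0.15,   0.25,   0.15],   # sd
        [40.0,  0.08,  -0.20,  -0.20],   # sds
        [15.0,  0.20,   0.15,   0.12],   # stt
        [35.0,  0.12,  -0.15,   0.30],   # sst
        [30.0,  0.10,   0.00,   0.20],   # aas   (constant in A)
        [45.0,  0.10,   0.20,   0.15],   # ass
        [30.0,  0.10,   0.00,   0.25],   # ast   (constant in A)
        [20.0,  0.15,  -0.20,   0.30],   # asd
        [30.0,  0.10,   0.00,   0.20],   # std   (constant in A)
        [25.0,  0.12,   0.20,  -0.30],   # asdas
        [30.0,  0.10,   0.00,   0.15],   # stdst (constant in A)
        [25.0, -0.10,   0.024,  0.018],  # dV_plus  (per Å³)
        [25.0, -0.10,  -0.030, -0.024],  # dV_minus (per Å³)
        [30.0, -0.12,   0.80,  -0.65],   # independent
    ])
    return ModelParameters(theta)


@dataclass
class GroundTruthModel:
    """A complete generating model: structures, potentials, parameters."""

    params: ModelParameters
    potentials: PotentialSet
    structures: dict[str, ProteinStructure]
    pdb_texts: dict[str, str]
    noise_sd: float
    seed: int


def make_ground_truth(
    n_structures: int = 6,
    n_residues: int = 40,
    noise_sd: float = 0.3,
    seed: int = 0,
    params: ModelParameters | None = None,
    scheme: BinningScheme | None = None,
) -> GroundTruthModel:
    """Build the standard synthetic world (structures → potentials → truth).

    Motifs cycle through helix, sheet, mixed so the descriptor space (all
    torsion domains, a range of accessibilities and pair distances) is
    populated.  Fully deterministic given the seed.
    """
    motifs = ("helix", "sheet", "mixed")
    pdb_texts: dict[str, str] = {}
    structures: dict[str, ProteinStructure] = {}
    for i in range(n_structures):
        sid = f"toy{i:02d}"
        text = make_toy_structure(n_residues, motif=motifs[i % 3],
                                  seed=seed * 1000 + i)
        pdb_texts[sid] = text
        structures[sid] = load_structure(text, structure_id=sid)
    potentials = derive_potentials(structures.values(), scheme=scheme)
    return GroundTruthModel(
        params=params or default_truth_parameters(),
        potentials=potentials, structures=structures, pdb_texts=pdb_texts,
        noise_sd=noise_sd, seed=seed)


@dataclass
class SimulatedDataset:
    """Records plus the noiseless ground-truth values they were drawn from."""

    records: list[MutantRecord]
    truth_ddg: np.ndarray
    fraction_destabilizing: float = field(init=False)

    def __post_init__(self):
        ddg = np.array([r.ddg_M for r in self.records])
        self.fraction_destabilizing = float(np.mean(ddg > 0.0)) if len(ddg) else 0.0


def simulate_mutant_dataset(
    truth: GroundTruthModel,
    n_mutants: int,
    seed: int = 0,
    noise_sd: float | None = None,
) -> SimulatedDataset:
    """Draw distinct mutations and simulate their measured ΔΔG values.

    Candidates run over every position and substitution with prolines
    excluded on both sides (mirroring the training filter).  ΔΔG_M is the
    ground-truth prediction plus Gaussian noise; candidates whose noiseless
    value already exceeds the +5 kcal/mol training cutoff are never drawn,
    and noise pushing a record past the cutoff is redrawn, so the returned
    set passes the dataset filter unchanged.
    """
    if noise_sd is None:
        noise_sd = truth.noise_sd
    rng = np.random.default_rng(seed)
    candidates = []
    for sid, structure in truth.structures.items():
        for res in structure.residues:
            if res.aa == "P":
                continue
            for s_m in C.AMINO_ACIDS:
                if s_m == res.aa or s_m == "P":
                    continue
                candidates.append((sid, res.index, s_m))
    if n_mutants > len(candidates):
        raise ValueError(
            f"requested {n_mutants} mutants but only {len(candidates)} "
            "distinct mutations exist")

    order = rng.permutation(len(candidates))
    records: list[MutantRecord] = []
    truths: list[float] = []
    for ci in order:
        if len(records) == n_mutants:
            break
        sid, pos, s_m = candidates[ci]
        structure = truth.structures[sid]
        res = structure.residues[pos]
        x, A = mutation_features(structure, pos, res.aa, s_m, truth.potentials)
        ddg_true = float((truth.params.coefficients(A) * x).sum())
        if ddg_true > DDG_TRAINING_CUTOFF:
            continue
        ddg_m = ddg_true
        if noise_sd > 0:
            for _ in range(1000):
                ddg_m = ddg_true + rng.normal(0.0, noise_sd)
                if ddg_m <= DDG_TRAINING_CUTOFF:
                    break
        records.append(MutantRecord(
            structure_id=sid, chain=res.chain, seq_number=res.seq_number,
            s_w=res.aa, s_m=s_m, ddg_M=ddg_m))
        truths.append(ddg_true)
    if len(records) < n_mutants:
        raise ValueError("not enough candidates below the training cutoff")
    return SimulatedDataset(records=records, truth_ddg=np.array(truths))


# ---------------------------------------------------------------------------
# Demo workspace
# ---------------------------------------------------------------------------

def make_demo(
    out_dir: str | Path,
    seed: int = 0,
    n_structures: int = 6,
    n_residues: int = 40,
    n_mutants: int = 600,
    noise_sd: float = 0.3,
) -> dict[str, Path]:
    """Write a complete self-contained workspace for the CLI and examples.

    Produces toy PDB structures, a simulated mutant table, the derived
    potential archive and the ground-truth model archive under ``out_dir``.
    """
    from .training import write_mutant_table

    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    truth = make_ground_truth(n_structures=n_structures, n_residues=n_residues,
                              noise_sd=noise_sd, seed=seed)
    paths: dict[str, Path] = {}
    for sid, text in truth.pdb_texts.items():
        p = out / "structures" / f"{sid}.pdb"
        p.write_text(text)
        paths[sid] = p
    data = simulate_mutant_dataset(truth, n_mutants=n_mutants, seed=seed + 1)
    paths["dataset"] = out / "dataset.tsv"
    write_mutant_table(data.records, paths["dataset"])
    paths["potentials"] = out / "potentials.json"
    truth.potentials.save(paths["potentials"])
    paths["truth_model"] = out / "truth_model.json"
    truth.params.save(paths["truth_model"],
                      extra={"role": "synthetic ground truth", "seed": seed,
                             "noise_sd": noise_sd})
    return paths
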