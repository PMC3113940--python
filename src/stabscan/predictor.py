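"""ΔΔG prediction: sigmoid-weighted combination of energy and volume terms.

The predicted folding free-energy change of a point mutation s_w → s_m is

    ΔΔG_P = Σ_{i=1..13} α_i(A) ΔΔW_i  +  α_14(A) ΔV_+  +  α_15(A) ΔV_-  +  α_16(A)

where the ΔΔW_i are the 13 statistical-potential differences
(:mod:`stabscan.potentials`), ΔV_± are the positive/negative parts of the
mutant-minus-wild-type residue volume difference, and every coefficient is
a logistic function of the *continuous* relative solvent accessibility A of
the wild-type residue:

    α_i(A) = f_i / (1 + exp(-r_i (A - c_i))) + b_i .

c_i is the inflection point (percent accessibility), r_i the slope (per
percent), f_i the scaling factor and b_i the vertical shift, so each
coefficient interpolates smoothly between a buried-core value (A → 0) and
an exposed-surface value (A → 100).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

from . import constants as C
from .potentials import PotentialSet, TERM_ORDER, delta_energy_terms
from .structure import ProteinStructure

__all__ = [
    "COEFFICIENT_NAMES",
    "N_COEFFICIENTS",
    "PARAM_KINDS",
    "ModelParameters",
    "Prediction",
    "sigmoid_weight",
    "volume_terms",
    "mutation_features",
    "predict_ddg",
    "systematic_scan",
    "parse_mutation_line",
    "format_prediction_line",
]

#: The 16 weighted contributions, in order: 13 potential terms, the two
#: volume terms, and the accessibility-dependent independent term.
COEFFICIENT_NAMES: tuple[str, ...] = TERM_ORDER + ("dV_plus", "dV_minus", "independent")
N_COEFFICIENTS = len(COEFFICIENT_NAMES)
#: Column order of the per-coefficient parameter quadruple.
PARAM_KINDS: tuple[str, ...] = ("c", "r", "f", "b")


@dataclass
class ModelParameters:
    """The 16 × 4 sigmoid parameters with an active/frozen mask.

    ``theta`` has shape (16, 4) with columns (c, r, f, b); ``active`` marks
    which slots a fit may move.  Frozen slots keep their stored values, so
    a coefficient with frozen f = 0 degenerates to the constant b.
    """

    theta: np.ndarray
    active: np.ndarray = field(default_factory=lambda: np.ones((N_COEFFICIENTS, 4), bool))

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.theta.shape != (N_COEFFICIENTS, 4):
            raise ValueError(f"theta must be {(N_COEFFICIENTS, 4)}")
        if self.active.shape != self.theta.shape:
            raise ValueError("active mask shape mismatch")

    @property
    def c(self) -> np.ndarray:
        return self.theta[:, 0]

    @property
    def r(self) -> np.ndarray:
        return self.theta[:, 1]

    @property
    def f(self) -> np.ndarray:
        return self.theta[:, 2]

    @property
    def b(self) -> np.ndarray:
        return self.theta[:, 3]

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def copy(self) -> "ModelParameters":
        return ModelParameters(self.theta.copy(), self.active.copy())

    def coefficients(self, A: float | np.ndarray) -> np.ndarray:
        """α_i(A) for all 16 coefficients; shape (16,) or (n, 16)."""
        A = np.asarray(A, dtype=float)
        z = self.r * (A[..., None] - self.c)
        return self.f * expit(z) + self.b

    # -- serialization (bit-exact round trip via float hex) -----------------
    def to_dict(self) -> dict:
        return {
            "format": "stabscan-model/1",
            "coefficients": list(COEFFICIENT_NAMES),
            "kinds": list(PARAM_KINDS),
            "theta_hex": [[v.hex() for v in row] for row in self.theta.astype(float)],
            "theta": self.theta.tolist(),   # human-readable mirror
            "active": self.active.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        if d.get("format") != "stabscan-model/1":
            raise ValueError("unrecognized model archive format")
        theta = np.array([[float.fromhex(v) for v in row] for row in d["theta_hex"]])
        return cls(theta, np.asarray(d["active"], dtype=bool))

    def save(self, path: str | Path, extra: dict | None = None) -> None:
        payload = self.to_dict()
        if extra:
            payload["provenance"] = extra
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


def sigmoid_weight(A: float, c: float, r: float, f: float, b: float) -> float:
    """One logistic coefficient α(A) = f / (1 + exp(-r (A - c))) + b."""
    return float(f * expit(r * (A - c)) + b)


def volume_terms(s_w: str, s_m: str) -> tuple[float, float]:
    """(ΔV₊, ΔV₋) in Å³: positive and negative parts of V_m − V_w.

    ΔV₊ > 0 models accommodating a larger side chain, ΔV₋ < 0 the creation
    of a cavity; at most one of the two is nonzero.
    """
    try:
        dv = C.RESIDUE_VOLUME[s_m] - C.RESIDUE_VOLUME[s_w]
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc.args[0]!r}") from exc
    return (dv, 0.0) if dv > 0 else (0.0, dv)


@dataclass
class Prediction:
    """One scored mutation with its full term breakdown."""

    chain: str
    seq_number: str
    s_w: str
    s_m: str
    ddg: float                   # kcal/mol
    A: float                     # accessibility used by the sigmoids
    breakdown: np.ndarray        # 16 weighted contributions, sums to ddg
    flags: tuple[str, ...] = ()

    @property
    def mutation(self) -> str:
        return f"{self.chain}{self.seq_number}{self.s_w}>{self.s_m}"


def mutation_features(
    structure: ProteinStructure,
    position: int,
    s_w: str,
    s_m: str,
    potentials: PotentialSet,
) -> tuple[np.ndarray, float]:
    """(16-vector of raw term values, accessibility A) for one mutation.

    The vector is [ΔΔW_1..13, ΔV₊, ΔV₋, 1]; weighting with α_i(A) and
    summing gives ΔΔG_P.
    """
    ddw = delta_energy_terms(structure, position, s_w, s_m, potentials)
    dvp, dvm = volume_terms(s_w, s_m)
    x = np.concatenate([ddw, [dvp, dvm, 1.0]])
    return x, structure.residues[position].a


def predict_ddg(
    structure: ProteinStructure,
    mutation: tuple[str, str, str, str],
    potentials: PotentialSet,
    params: ModelParameters,
) -> Prediction:
    """Predict ΔΔG_P for one mutation given as (chain, seq_number, wt, mut)."""
    chain, seq_number, s_w, s_m = mutation
    res = structure.find(chain, seq_number)
    return _predict_at(structure, res.index, s_w, s_m, potentials, params)


def _predict_at(structure: ProteinStructure, position: int, s_w: str, s_m: str,
                potentials: PotentialSet, params: ModelParameters) -> Prediction:
    x, A = mutation_features(structure, position, s_w, s_m, potentials)
    alpha = params.coefficients(A)
    breakdown = alpha * x
    flags = ()
    if "P" in (s_w, s_m):
        # prolines break backbone assumptions; the model was never meant to
        # be trained on them, so the value is returned but marked
        flags = ("proline_low_confidence",)
    res = structure.residues[position]
    return Prediction(chain=res.chain, seq_number=res.seq_number, s_w=s_w,
                      s_m=s_m, ddg=float(breakdown.sum()), A=A,
                      breakdown=breakdown, flags=flags)


def systematic_scan(
    structure: ProteinStructure,
    potentials: PotentialSet,
    params: ModelParameters,
    order: str = "sequential",
) -> list[Prediction]:
    """All 19 single-site mutations at every residue of the structure.

    ``order='sequential'`` sorts by (chain, position, mutant letter);
    ``order='by_ddg'`` sorts by predicted ΔΔG_P ascending (most stabilizing
    first).
    """
    if order not in ("sequential", "by_ddg"):
        raise ValueError(f"unknown ordering {order!r}")
    preds: list[Prediction] = []
    for res in structure.residues:
        for s_m in C.AMINO_ACIDS:
            if s_m == res.aa:
                continue
            preds.append(_predict_at(structure, res.index, res.aa, s_m,
                                     potentials, params))
    if order == "by_ddg":
        preds.sort(key=lambda p: (p.ddg, p.chain, p.seq_number, p.s_m))
    return preds


# ---------------------------------------------------------------------------
# Plain-text mutation interchange
# ---------------------------------------------------------------------------

def parse_mutation_line(line: str) -> tuple[str, str, str, str]:
    """Parse one 'CHAIN RESNUM WT MUT' token list; '#' starts a comment."""
    body = line.split("#", 1)[0].strip()
    parts = body.split()
    if len(parts) != 4:
        raise ValueError(f"malformed mutation line: {line.rstrip()!r}")
    chain, seq_number, s_w, s_m = parts
    s_w, s_m = s_w.upper(), s_m.upper()
    for aa in (s_w, s_m):
        if aa not in C.AA_INDEX:
            raise ValueError(f"unknown amino acid {aa!r} in {line.rstrip()!r}")
    return chain, seq_number, s_w, s_m


def read_mutation_list(path: str | Path) -> list[tuple[str, str, str, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.split("#", 1)[0].strip():
            continue
        out.append(parse_mutation_line(line))
    return out


def format_prediction_line(p: Prediction) -> str:
    flags = ",".join(p.flags) if p.flags else "-"
    return f"{p.chain}\t{p.seq_number}\t{p.s_w}\t{p.s_m}\t{p.ddg:.4f}\t{flags}"


def write_predictions(preds: Iterable[Prediction], path: str | Path) -> None:
    lines = ["CHAIN\tRESNUM\tWT\tMUT\tDDG_PRED\tFLAGS"]
    lines += [format_prediction_line(p) for p in preds]
    Path(path).write_text("\n".join(lines) + "\n")
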