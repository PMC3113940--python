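"""Per-position sequence-optimality scoring from systematic mutation scans.

The optimality score of position i is the sum of the predicted stability
changes of all *stabilizing* mutations there:

    Γ_i = Σ_m ΔΔG_P(w_i → m) · H(−ΔΔG_P(w_i → m)),

where m runs over the 19 possible substitutions and H is the Heaviside
step (strict: a prediction of exactly zero contributes nothing).  Γ is
never positive; Γ = 0 marks a position where every substitution is
predicted destabilizing, while strongly negative Γ marks a structural
weakness — a position the sequence leaves far from stability-optimal,
often for functional reasons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import constants as C
from .predictor import Prediction

__all__ = [
    "PositionScore",
    "GammaProfile",
    "gamma_profile",
    "flag_weak_positions",
    "stratify_gamma",
    "render_profile",
    "write_gamma_table",
]

#: A position is conventionally called non-optimal (a structural weakness)
#: when Γ is at or below this many kcal/mol.
WEAKNESS_THRESHOLD = -5.0


@dataclass
class PositionScore:
    """Γ and its contributing stabilizing mutations for one position."""

    chain: str
    seq_number: str
    aa: str
    gamma: float                       # kcal/mol, ≤ 0
    contributing: tuple[tuple[str, float], ...]   # (mutant aa, ΔΔG_P < 0)
    n_predictions: int
    A: float = float("nan")

    @property
    def partial(self) -> bool:
        """True when fewer than the full 19 substitutions were scanned."""
        return self.n_predictions < C.N_AA - 1

    @property
    def is_core(self) -> bool:
        return self.A < C.CORE_SURFACE_THRESHOLD


@dataclass
class GammaProfile:
    positions: list[PositionScore] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def gamma(self) -> np.ndarray:
        return np.array([p.gamma for p in self.positions])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [p.chain for p in self.positions],
            "seq_number": [p.seq_number for p in self.positions],
            "aa": [p.aa for p in self.positions],
            "gamma": [p.gamma for p in self.positions],
            "n_stabilizing": [len(p.contributing) for p in self.positions],
            "partial": [p.partial for p in self.positions],
        })


def gamma_profile(scan: Iterable[Prediction]) -> GammaProfile:
    """Aggregate a systematic scan into a per-position Γ profile.

    Predictions are grouped by (chain, position); Γ is the sum of the
    strictly negative ΔΔG_P values, whose identities are retained.
    Positions covered by fewer than 19 predictions are flagged partial.
    """
    by_pos: dict[tuple[str, str], list[Prediction]] = {}
    order: list[tuple[str, str]] = []
    for p in scan:
        key = (p.chain, p.seq_number)
        if key not in by_pos:
            by_pos[key] = []
            order.append(key)
        by_pos[key].append(p)

    profile = GammaProfile()
    for key in order:
        preds = by_pos[key]
        contributing = tuple((p.s_m, p.ddg) for p in preds if p.ddg < 0.0)
        profile.positions.append(PositionScore(
            chain=key[0], seq_number=key[1], aa=preds[0].s_w,
            gamma=float(sum(d for _, d in contributing)),
            contributing=contributing,
            n_predictions=len(preds),
            A=preds[0].A,
        ))
    return profile


def flag_weak_positions(profile: GammaProfile,
                        threshold: float = WEAKNESS_THRESHOLD) -> list[PositionScore]:
    """Positions with Γ ≤ threshold, most negative first."""
    flagged = [p for p in profile.positions if p.gamma <= threshold]
    return sorted(flagged, key=lambda p: p.gamma)


def stratify_gamma(
    gamma: Sequence[float] | GammaProfile,
    labels: Sequence[str],
    core_surface: Sequence[str] | None = None,
    thresholds: Sequence[float] = (0.0, -0.25, -0.5, -1.0, -2.0, -3.0, -5.0),
) -> pd.DataFrame:
    """Fraction of positions with Γ strictly below each threshold, per class.

    ``labels`` assigns each position to a user-supplied class (for example
    catalytic vs. other); ``core_surface`` optionally splits each class by
    burial.  Each (threshold, label, {all, core, surface}) cell reports the
    fraction and the underlying counts; empty cells are flagged undefined.
    """
    if isinstance(gamma, GammaProfile):
        if core_surface is None:
            core_surface = ["core" if p.is_core else "surface"
                            for p in gamma.positions]
        gamma = gamma.gamma
    g = np.asarray(gamma, dtype=float)
    labels = np.asarray(labels)
    if len(labels) != len(g):
        raise ValueError("labels must cover all positions")
    if core_surface is None:
        core_surface = np.full(len(g), "surface")
    burial = np.asarray(core_surface)

    rows = []
    for thr in thresholds:
        below = g < thr
        for lab in sorted(set(labels.tolist())):
            in_lab = labels == lab
            for stratum in ("all", "core", "surface"):
                sel = in_lab if stratum == "all" else in_lab & (burial == stratum)
                n = int(sel.sum())
                rows.append({
                    "threshold": thr, "label": lab, "stratum": stratum,
                    "n": n,
                    "n_below": int((below & sel).sum()),
                    "fraction": float((below & sel).sum() / n) if n else None,
                    "undefined": n == 0,
                })
    return pd.DataFrame(rows)


def write_gamma_table(profile: GammaProfile, path: str | Path) -> None:
    """Tab-separated Γ output: CHAIN RESNUM WT GAMMA N_STABILIZING."""
    lines = ["CHAIN\tRESNUM\tWT\tGAMMA\tN_STABILIZING"]
    for p in profile.positions:
        lines.append(f"{p.chain}\t{p.seq_number}\t{p.aa}\t{p.gamma:.4f}\t"
                     f"{len(p.contributing)}")
    Path(path).write_text("\n".join(lines) + "\n")


def render_profile(
    profile: GammaProfile,
    table_path: str | Path,
    plot_path: str | Path | None = None,
    secondary_structure: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Emit the machine-readable Γ table and, optionally, a profile plot.

    The per-position track plots Γ against sequence position; when
    secondary-structure labels are supplied the bars are coloured by class
    (helix red, strand blue, coil green, following the usual convention).
    """
    write_gamma_table(profile, table_path)
    df = profile.table()
    if plot_path is not None and len(profile) > 0:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        colors = None
        if secondary_structure is not None:
            palette = {"H": "#c44", "helix": "#c44",
                       "E": "#46c", "strand": "#46c", "sheet": "#46c"}
            colors = [palette.get(ss, "#4a4") for ss in secondary_structure]
        fig, ax = plt.subplots(figsize=(max(6, len(profile) / 8), 3))
        ax.bar(np.arange(len(profile)), profile.gamma, color=colors or "#557")
        ax.axhline(WEAKNESS_THRESHOLD, color="k", lw=0.8, ls="--")
        ax.set_xlabel("position")
        ax.set_ylabel(r"$\Gamma$ (kcal/mol)")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
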