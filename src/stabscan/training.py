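"""Fitting the sigmoid weights to measured ΔΔG data, and validation metrics.

The trainable model (:mod:`stabscan.predictor`) is linear in the 16 raw
term values and nonlinear only through the logistic accessibility
dependence of each coefficient.  Training minimizes the root mean square
error

    σ = sqrt( (1/N) Σ_m (ΔΔG_M,m − ΔΔG_P,m)² )

over the active subset of the 64 parameters (16 quadruples c, r, f, b) by
bounded nonlinear least squares with analytic gradients, restarted from
several data-driven random initializations.

The module also provides the validation protocol used to report
performance: k-fold cross-validation, outlier-trimmed metrics, a second
training round with consistently mispredicted training mutants removed,
RMSE binned along predicted or measured ΔΔG, specificity with respect to
stabilizing mutations, and the shuffled/constant reference baselines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from . import constants as C
from .potentials import PotentialSet
from .predictor import (ModelParameters, N_COEFFICIENTS, PARAM_KINDS,
                        mutation_features)
from .structure import ProteinStructure

__all__ = [
    "MutantRecord",
    "DesignMatrix",
    "FitResult",
    "CVResult",
    "read_mutant_table",
    "write_mutant_table",
    "filter_dataset",
    "build_design",
    "fit_parameters",
    "reduce_parameters",
    "cross_validate",
    "retrain_without_training_outliers",
    "evaluate",
    "binned_rmse",
    "stabilizing_specificity",
    "baselines",
    "shuffle_baseline_distribution",
    "format_report",
]

#: Maximum measured destabilization retained for training (kcal/mol);
#: larger changes are likely to involve structural rearrangements the
#: fixed-backbone model cannot describe.
DDG_TRAINING_CUTOFF = 5.0

KNOWN_FLAGS = ("heme_protein", "pseudo_wild_type")

# optimizer bounds per parameter kind (c, r, f, b)
_BOUND_LO = np.array([0.0, -5.0, -60.0, -60.0])
_BOUND_HI = np.array([100.0, 5.0, 60.0, 60.0])
_X_SCALE = np.array([10.0, 0.1, 1.0, 1.0])


@dataclass(frozen=True)
class MutantRecord:
    """One experimentally characterized point mutation."""

    structure_id: str
    chain: str
    seq_number: str
    s_w: str
    s_m: str
    ddg_M: float                 # measured, kcal/mol
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.s_w == self.s_m:
            raise ValueError("wild-type and mutant types must differ")
        if not math.isfinite(self.ddg_M):
            raise ValueError("measured ddG must be finite")


# ---------------------------------------------------------------------------
# Dataset I/O and filtering
# ---------------------------------------------------------------------------

def read_mutant_table(path: str | Path) -> list[MutantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "resnum": str})
    records = []
    for row in df.itertuples(index=False):
        flags = () if row.flags in ("-", "", None) else tuple(str(row.flags).split(";"))
        records.append(MutantRecord(
            structure_id=str(row.structure_id), chain=str(row.chain),
            seq_number=str(row.resnum), s_w=str(row.wt), s_m=str(row.mut),
            ddg_M=float(row.ddg_M), flags=flags))
    return records


def write_mutant_table(records: Iterable[MutantRecord], path: str | Path) -> None:
    rows = [{
        "structure_id": r.structure_id, "chain": r.chain, "resnum": r.seq_number,
        "wt": r.s_w, "mut": r.s_m, "ddg_M": r.ddg_M,
        "flags": ";".join(r.flags) if r.flags else "-",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def filter_dataset(
    records: Sequence[MutantRecord],
) -> tuple[list[MutantRecord], dict[str, int]]:
    """Apply the training exclusion rules; returns (retained, report).

    Excluded are mutations involving a proline (either side), mutations
    destabilizing by more than 5 kcal/mol, and records flagged as coming
    from heme proteins or pseudo-wild-type constructs.  The report counts
    exclusions by the first rule that fired.
    """
    retained: list[MutantRecord] = []
    report = {"flagged": 0, "proline": 0, "ddg_above_cutoff": 0, "retained": 0}
    for r in records:
        if any(f in KNOWN_FLAGS for f in r.flags):
            report["flagged"] += 1
        elif "P" in (r.s_w, r.s_m):
            report["proline"] += 1
        elif r.ddg_M > DDG_TRAINING_CUTOFF:
            report["ddg_above_cutoff"] += 1
        else:
            retained.append(r)
    report["retained"] = len(retained)
    return retained, report


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Precomputed raw features for a mutant set.

    ``X`` holds the 16 raw term values per mutant, ``A`` the wild-type
    accessibilities, ``y`` the measured ΔΔG values.
    """

    X: np.ndarray
    A: np.ndarray
    y: np.ndarray
    records: tuple[MutantRecord, ...] = ()

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "DesignMatrix":
        recs = tuple(self.records[i] for i in idx) if self.records else ()
        return DesignMatrix(self.X[idx], self.A[idx], self.y[idx], recs)


def build_design(
    records: Sequence[MutantRecord],
    structures: dict[str, ProteinStructure],
    potentials: PotentialSet,
) -> DesignMatrix:
    """Compute the (X, A, y) design for a mutant set against its structures."""
    X = np.empty((len(records), N_COEFFICIENTS))
    A = np.empty(len(records))
    y = np.empty(len(records))
    for m, rec in enumerate(records):
        try:
            structure = structures[rec.structure_id]
        except KeyError as exc:
            raise KeyError(f"no structure loaded for {rec.structure_id!r}") from exc
        res = structure.find(rec.chain, rec.seq_number)
        X[m], A[m] = mutation_features(structure, res.index, rec.s_w, rec.s_m,
                                       potentials)
        y[m] = rec.ddg_M
    return DesignMatrix(X, A, y, tuple(records))


# ---------------------------------------------------------------------------
# Model math
# ---------------------------------------------------------------------------

def model_predictions(params: ModelParameters, design: DesignMatrix) -> np.ndarray:
    """ΔΔG_P for every row of the design."""
    alpha = params.coefficients(design.A)     # (n, 16)
    return (alpha * design.X).sum(axis=1)


def sigma_of(params: ModelParameters, design: DesignMatrix) -> float:
    err = design.y - model_predictions(params, design)
    return float(np.sqrt(np.mean(err ** 2)))


def _pack(theta: np.ndarray, active: np.ndarray) -> np.ndarray:
    return theta[active]


def _unpack(vec: np.ndarray, template: np.ndarray, active: np.ndarray) -> np.ndarray:
    theta = template.copy()
    theta[active] = vec
    return theta


def _residual_and_jac(theta: np.ndarray, design: DesignMatrix,
                      active: np.ndarray):
    c, r, f, b = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
    Am = design.A[:, None] - c                  # (n, 16)
    sig = expit(r * Am)
    alpha = f * sig + b
    resid = design.y - (alpha * design.X).sum(axis=1)
    dsig = sig * (1.0 - sig)
    # d pred / d theta, shape (n, 16, 4); residual derivative is its negative
    dpred = np.empty((len(design), N_COEFFICIENTS, 4))
    dpred[:, :, 0] = -design.X * f * dsig * r     # d/dc
    dpred[:, :, 1] = design.X * f * dsig * Am     # d/dr
    dpred[:, :, 2] = design.X * sig               # d/df
    dpred[:, :, 3] = design.X                     # d/db
    jac = -dpred[:, active]
    return resid, jac


@dataclass
class FitResult:
    """Outcome of a parameter fit."""

    params: ModelParameters
    sigma_train: float           # kcal/mol, recomputable from params
    history: list[float]         # best objective after each restart (nonincreasing)
    seed: int
    converged: bool
    n_records: int


def fit_parameters(
    design: DesignMatrix,
    init_seed: int = 0,
    restarts: int = 8,
    init: ModelParameters | None = None,
    active: np.ndarray | None = None,
    max_nfev: int = 600,
) -> FitResult:
    """Fit the active sigmoid parameters by nonlinear least squares.

    Each restart draws a fresh data-driven initialization (vertical shifts
    from an ordinary least-squares solve of the linearized model, inflection
    points and slopes from seeded uniform draws) and runs a bounded
    trust-region solve with analytic Jacobian; the best restart wins.
    Passing ``init`` adds a warm start as restart 0 and supplies the values
    of frozen slots.  Deterministic given (init_seed, restarts).
    """
    n = len(design)
    if init is not None:
        template = init.theta.copy()
        mask = init.active if active is None else np.asarray(active, bool)
    else:
        template = _default_template()
        mask = (np.ones((N_COEFFICIENTS, 4), bool) if active is None
                else np.asarray(active, bool))
    n_active = int(mask.sum())
    if n and n < 10 * n_active:
        warnings.warn(
            f"only {n} records for {n_active} active parameters; "
            "fit may be underdetermined", stacklevel=2)

    lo = np.broadcast_to(_BOUND_LO, (N_COEFFICIENTS, 4))[mask]
    hi = np.broadcast_to(_BOUND_HI, (N_COEFFICIENTS, 4))[mask]
    x_scale = np.broadcast_to(_X_SCALE, (N_COEFFICIENTS, 4))[mask]

    beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)

    best = None
    history: list[float] = []
    converged = False
    starts = ([template] if init is not None else []) + [
        _random_init(template, mask, beta,
                     np.random.default_rng([init_seed, k]))
        for k in range(restarts)
    ]
    for theta0 in starts:
        x0 = np.clip(_pack(theta0, mask), lo, hi)
        cache: dict = {}

        def _eval(v):
            key = v.tobytes()
            if cache.get("key") != key:
                r, j = _residual_and_jac(_unpack(v, template, mask), design, mask)
                cache.update(key=key, r=r, j=j)
            return cache

        res = least_squares(
            lambda v: _eval(v)["r"], x0, jac=lambda v: _eval(v)["j"],
            bounds=(lo, hi), x_scale=x_scale, method="trf",
            ftol=1e-11, xtol=1e-11, gtol=1e-11, max_nfev=max_nfev)
        sigma = float(np.sqrt(2.0 * res.cost / max(n, 1)))
        if best is None or sigma < best[0]:
            best = (sigma, res.x)
        if res.status > 0:
            converged = True
        history.append(best[0])

    theta = _unpack(best[1], template, mask)
    params = ModelParameters(theta, mask.copy())
    return FitResult(params=params, sigma_train=sigma_of(params, design),
                     history=history, seed=init_seed, converged=converged,
                     n_records=n)


def _default_template() -> np.ndarray:
    theta = np.zeros((N_COEFFICIENTS, 4))
    theta[:, 0] = 30.0    # c: mid-range inflection
    theta[:, 1] = 0.1     # r: gentle slope
    return theta


def _random_init(template: np.ndarray, mask: np.ndarray, beta: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    theta = template.copy()
    c0 = rng.uniform(5.0, 60.0, N_COEFFICIENTS)
    r0 = rng.uniform(-0.35, 0.35, N_COEFFICIENTS)
    f0 = rng.normal(0.0, 0.3, N_COEFFICIENTS) * (1.0 + np.abs(beta))
    b0 = beta + rng.normal(0.0, 0.1, N_COEFFICIENTS)
    draw = np.column_stack([c0, r0, f0, b0])
    theta[mask] = draw[mask]
    return theta


# ---------------------------------------------------------------------------
# Parameter reduction
# ---------------------------------------------------------------------------

def reduce_parameters(
    design: DesignMatrix,
    fit: FitResult,
    n_resamples: int = 20,
    cv_threshold: float = 1.0,
    seed: int = 0,
    refit_restarts: int = 1,
) -> FitResult:
    """Iteratively freeze the most uncertain parameters.

    Uncertainty of an active slot is its coefficient of variation across
    warm-started refits on bootstrap resamples of the data.  While any slot
    exceeds ``cv_threshold``, the worst one is frozen — a scaling factor f
    to 0 (collapsing its sigmoid to the constant b), any other slot to its
    bootstrap mean — and the model is refit.  The active count strictly
    decreases each iteration.
    """
    if not np.isfinite(cv_threshold):
        return fit
    current = fit
    rng = np.random.default_rng(seed)
    n = len(design)
    iteration = 0
    while current.params.n_active > 0:
        thetas = np.empty((n_resamples, N_COEFFICIENTS, 4))
        for k in range(n_resamples):
            idx = rng.integers(0, n, size=n)
            boot = design.subset(idx)
            refit = fit_parameters(boot, init_seed=int(rng.integers(2**31)),
                                   restarts=refit_restarts - 1,
                                   init=current.params)
            thetas[k] = refit.params.theta
        mean = thetas.mean(axis=0)
        std = thetas.std(axis=0)
        cv = std / (np.abs(mean) + 1e-12)
        cv[~current.params.active] = -np.inf
        worst = np.unravel_index(int(np.argmax(cv)), cv.shape)
        if not np.isfinite(cv[worst]) or cv[worst] <= cv_threshold:
            break
        theta = current.params.theta.copy()
        active = current.params.active.copy()
        i, kind = worst
        theta[i, kind] = 0.0 if PARAM_KINDS[kind] == "f" else mean[i, kind]
        active[i, kind] = False
        frozen = ModelParameters(theta, active)
        current = fit_parameters(design, init_seed=fit.seed + 1000 + iteration,
                                 restarts=refit_restarts, init=frozen)
        iteration += 1
    return current


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """State of a k-fold cross-validation run."""

    design: DesignMatrix
    k: int
    seed: int
    restarts: int
    fold_of: np.ndarray                 # validation-fold index per record
    fold_params: list[ModelParameters]
    run_predictions: np.ndarray         # (k, n): every record scored by each run
    folds: list[dict]                   # per-fold metric dicts
    averages: dict                      # "Average 1" row
    trim_fraction: float = 0.10


def cross_validate(
    design: DesignMatrix,
    k: int = 5,
    seed: int = 0,
    restarts: int = 4,
    trim_fraction: float = 0.10,
    groups: Sequence[str] | None = None,
) -> CVResult:
    """k-fold cross-validation of the sigmoid-weight model.

    Records are partitioned at random (seeded) into k validation folds;
    each run fits on the other k−1 folds and scores both its training and
    validation sets, with and without trimming the ``trim_fraction`` worst
    predictions.  ``groups`` optionally keeps all records of one protein
    inside the same fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    n = len(design)
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if groups is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold_of[chunk] = f
    else:
        uniq = sorted(set(groups))
        gperm = rng.permutation(len(uniq))
        gfold: dict[str, int] = {}
        for f, chunk in enumerate(np.array_split(gperm, k)):
            for gi in chunk:
                gfold[uniq[int(gi)]] = f
        fold_of = np.array([gfold[g] for g in groups])
    if min(np.bincount(fold_of, minlength=k)) < 2:
        raise ValueError("a fold has fewer than 2 records")

    fold_params: list[ModelParameters] = []
    run_predictions = np.empty((k, n))
    folds = []
    for f in range(k):
        val_idx = np.flatnonzero(fold_of == f)
        train_idx = np.flatnonzero(fold_of != f)
        fit = fit_parameters(design.subset(train_idx), init_seed=seed * 1000 + f,
                             restarts=restarts)
        fold_params.append(fit.params)
        run_predictions[f] = model_predictions(fit.params, design)
        folds.append(_fold_metrics(design, run_predictions[f], train_idx,
                                   val_idx, trim_fraction))
    averages = _average_metrics(folds)
    return CVResult(design=design, k=k, seed=seed, restarts=restarts,
                    fold_of=fold_of, fold_params=fold_params,
                    run_predictions=run_predictions, folds=folds,
                    averages=averages, trim_fraction=trim_fraction)


def _fold_metrics(design, preds, train_idx, val_idx, trim_fraction):
    out = {"n_train": len(train_idx), "n_val": len(val_idx)}
    for tag, idx in (("d", train_idx), ("c", val_idx)):
        full = evaluate(preds[idx], design.y[idx])
        trimmed = evaluate(preds[idx], design.y[idx], trim_fraction=trim_fraction)
        out[f"R_{tag}"] = full["R"]
        out[f"sigma_{tag}"] = full["sigma"]
        out[f"R_{tag}_trim"] = trimmed["R"]
        out[f"sigma_{tag}_trim"] = trimmed["sigma"]
    return out


def _average_metrics(folds: list[dict]) -> dict:
    keys = [k for k in folds[0] if not k.startswith("n_")]
    return {k: float(np.mean([f[k] for f in folds])) for k in keys}


def retrain_without_training_outliers(
    cv: CVResult,
    cutoff: float = 1.5,
) -> dict:
    """Second training round with consistently mispredicted mutants removed.

    A record is an outlier when |ΔΔG_P − ΔΔG_M| exceeds ``cutoff`` in *every*
    one of the initial runs (the intersection of the per-run outlier sets).
    Outliers are dropped from the training folds only; validation folds are
    unchanged, so the resulting "Average 2" validation metrics are directly
    comparable with the initial ones.
    """
    err = np.abs(cv.run_predictions - cv.design.y[None, :])
    outliers = np.flatnonzero((err > cutoff).all(axis=0))
    out_set = set(outliers.tolist())

    folds = []
    for f in range(cv.k):
        val_idx = np.flatnonzero(cv.fold_of == f)
        train_idx = np.array([i for i in np.flatnonzero(cv.fold_of != f)
                              if i not in out_set], dtype=int)
        fit = fit_parameters(cv.design.subset(train_idx),
                             init_seed=cv.seed * 1000 + f, restarts=cv.restarts)
        preds = model_predictions(fit.params, cv.design)
        folds.append(_fold_metrics(cv.design, preds, train_idx, val_idx,
                                   cv.trim_fraction))
    return {
        "outlier_indices": outliers,
        "n_outliers": len(outliers),
        "folds": folds,
        "averages": _average_metrics(folds),
    }


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate(pred: np.ndarray, meas: np.ndarray,
             trim_fraction: float = 0.0) -> dict:
    """Pearson R and RMSE σ, optionally after trimming the worst pairs.

    Trimming removes the ⌈trim_fraction·N⌉ pairs with largest absolute
    error before computing both metrics.  With zero variance in either
    vector R is undefined (None) and flagged.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if len(pred) != len(meas):
        raise ValueError("length mismatch")
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    n = len(pred)
    if trim_fraction > 0:
        drop = math.ceil(trim_fraction * n)
        keep = np.argsort(np.abs(pred - meas), kind="stable")[: n - drop]
        pred, meas = pred[keep], meas[keep]
    err = pred - meas
    sigma = float(np.sqrt(np.mean(err ** 2)))
    if np.std(pred) == 0.0 or np.std(meas) == 0.0:
        return {"R": None, "sigma": sigma, "n_used": len(pred),
                "zero_variance": True}
    R = float(np.corrcoef(pred, meas)[0, 1])
    return {"R": R, "sigma": sigma, "n_used": len(pred), "zero_variance": False}


def binned_rmse(pred: np.ndarray, meas: np.ndarray, axis: str = "predicted",
                width: float = 0.25, min_count: int = 10) -> pd.DataFrame:
    """RMSE per ΔΔG interval along the predicted or measured axis.

    Pairs are partitioned into non-overlapping bins of ``width`` kcal/mol
    on the chosen axis; bins holding fewer than ``min_count`` pairs are
    marked dismissed (their σ is still reported for audit).
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if axis not in ("predicted", "measured"):
        raise ValueError("axis must be 'predicted' or 'measured'")
    v = pred if axis == "predicted" else meas
    ids = np.floor(v / width).astype(int)
    rows = []
    for b in sorted(set(ids.tolist())):
        sel = ids == b
        err = pred[sel] - meas[sel]
        rows.append({
            "bin_left": b * width, "bin_right": (b + 1) * width,
            "n": int(sel.sum()),
            "sigma": float(np.sqrt(np.mean(err ** 2))),
            "retained": bool(sel.sum() >= min_count),
        })
    return pd.DataFrame(rows)


def stabilizing_specificity(pred: np.ndarray, meas: np.ndarray,
                            pred_threshold: float) -> dict:
    """Fraction of predicted-stabilizing mutations that are truly stabilizing.

    Selects pairs with ΔΔG_P < pred_threshold and reports the fraction with
    ΔΔG_M < 0.  Undefined (flagged) when nothing is selected.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    sel = pred < pred_threshold
    n_sel = int(sel.sum())
    if n_sel == 0:
        return {"fraction": None, "n_selected": 0, "undefined": True}
    frac = float(np.mean(meas[sel] < 0.0))
    return {"fraction": frac, "n_selected": n_sel, "undefined": False}


def baselines(meas: np.ndarray, seed: int = 0) -> dict:
    """Reference predictors: shuffled measurements and the constant mean.

    The random baseline scores a seeded permutation of the measured values
    against the originals; the constant baseline σ is the population
    standard deviation of the measurements (the RMSE of always predicting
    their mean).
    """
    meas = np.asarray(meas, dtype=float)
    if len(meas) < 3:
        raise ValueError("need at least 3 values")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(meas)
    shuffled = evaluate(perm, meas)
    return {
        "random_shuffle": {"R": shuffled["R"], "sigma": shuffled["sigma"]},
        "constant_mean": {"sigma": float(np.std(meas))},
    }


def shuffle_baseline_distribution(meas: np.ndarray, n_seeds: int = 1000,
                                  seed: int = 0) -> np.ndarray:
    """Null distribution of the shuffle-baseline correlation over seeds."""
    meas = np.asarray(meas, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_seeds)
    for i in range(n_seeds):
        out[i] = float(np.corrcoef(rng.permutation(meas), meas)[0, 1])
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def format_report(cv: CVResult, second_round: dict | None = None,
                  baseline: dict | None = None) -> str:
    """Plain-text validation report: per-run rows plus average rows."""
    def fmt(x):
        return "  -  " if x is None else f"{x:5.2f}"

    lines = [
        "k-fold validation report",
        f"n = {len(cv.design)}   k = {cv.k}   seed = {cv.seed}",
        "",
        "            All mutants          Excl. 10% outliers",
        "            R_d/R_c  s_d/s_c     R_d/R_c  s_d/s_c",
    ]
    if baseline:
        lines.append(
            f"ConstMean     -      -/{baseline['constant_mean']['sigma']:4.2f}")
        lines.append(
            f"Shuffle     {fmt(baseline['random_shuffle']['R'])}/-  "
            f"-/{baseline['random_shuffle']['sigma']:4.2f}")
    for i, f in enumerate(cv.folds, 1):
        lines.append(
            f"Run {i}      {fmt(f['R_d'])}/{fmt(f['R_c'])} "
            f"{fmt(f['sigma_d'])}/{fmt(f['sigma_c'])}   "
            f"{fmt(f['R_d_trim'])}/{fmt(f['R_c_trim'])} "
            f"{fmt(f['sigma_d_trim'])}/{fmt(f['sigma_c_trim'])}")
    a = cv.averages
    lines.append(
        f"Average 1  {fmt(a['R_d'])}/{fmt(a['R_c'])} "
        f"{fmt(a['sigma_d'])}/{fmt(a['sigma_c'])}   "
        f"{fmt(a['R_d_trim'])}/{fmt(a['R_c_trim'])} "
        f"{fmt(a['sigma_d_trim'])}/{fmt(a['sigma_c_trim'])}")
    if second_round is not None:
        a2 = second_round["averages"]
        lines.append(
            f"Average 2    -  /{fmt(a2['R_c'])}   -  /{fmt(a2['sigma_c'])}   "
            f"  -  /{fmt(a2['R_c_trim'])}   -  /{fmt(a2['sigma_c_trim'])}")
        lines.append(f"(second round: {second_round['n_outliers']} "
                     "training outliers removed; validation sets unchanged)")
    return "\n".join(lines) + "\n"
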