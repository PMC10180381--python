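"""Deviation statistics and exact L1 refitting of the dispersion scaling factors.

Because the dispersion energy is linear in (S6, S8), the mean absolute
deviation across clusters,

    MAE(S6, S8) = mean_i | d_i − S6·e6_i − S8·e8_i |,

is a convex piecewise-linear function of the factors. With one factor fixed
the exact minimizer over the other lies at a breakpoint s = residual_i / e_i
(or a bound), so a finite candidate scan yields the global 1-D optimum —
no iterative solver, no tolerance. The joint fit alternates these exact 1-D
minimizations and finishes with an exact linear-programming polish, since
coordinate descent on a polyhedral objective can stall at a vertex that is
optimal along each axis but not jointly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .dispersion import DispersionComponents, ScalingFactors
from .exceptions import DataError
from .interaction import DeviationRecord, apply_dispersion

__all__ = [
    "ErrorStats",
    "FitResult",
    "error_stats",
    "mae_per_molecule",
    "display_round",
    "pair_records",
    "optimize_s8",
    "optimize_s6_s8",
    "scan_s8",
    "report_tables",
]

_STATS_TOL = 1e-9


@dataclass(frozen=True)
class ErrorStats:
    """Deviation statistics over one homogeneous cluster size.

    err: mean signed deviation (kcal/mol); mse: mean squared deviation
    (kcal²/mol²); mae: mean absolute deviation (kcal/mol); mae_per_mol:
    mae divided by the monomer count.
    """

    err: float
    mse: float
    mae: float
    mae_per_mol: float
    n_configs: int
    n_monomers: int

    def __post_init__(self) -> None:
        # arithmetic identities of L1/L2 means; violations indicate a bug upstream
        if self.mae < abs(self.err) - _STATS_TOL:
            raise DataError("ErrorStats violates MAE >= |Err|")
        if self.mse < self.err**2 - _STATS_TOL:
            raise DataError("ErrorStats violates MSE >= Err²")
        if self.mae**2 > self.mse + _STATS_TOL:
            raise DataError("ErrorStats violates MAE² <= MSE")


def error_stats(devs: Sequence[DeviationRecord]) -> ErrorStats:
    """Err/MSE/MAE/MAE-per-molecule of a homogeneous set of deviation records."""
    if not devs:
        raise DataError("cannot compute statistics of an empty deviation set")
    sizes = {d.n_monomers for d in devs}
    if len(sizes) != 1:
        raise DataError(
            f"mixed cluster sizes {sorted(sizes)}: group records by n_monomers first"
        )
    n_mono = sizes.pop()
    d = np.array([r.deviation for r in devs])
    mae = float(np.mean(np.abs(d)))
    return ErrorStats(
        err=float(np.mean(d)),
        mse=float(np.mean(d**2)),
        mae=mae,
        mae_per_mol=mae / n_mono,
        n_configs=len(devs),
        n_monomers=n_mono,
    )


def mae_per_molecule(mae: float, n_monomers: int) -> float:
    """Per-monomer normalization of a per-cluster MAE."""
    if n_monomers < 1:
        raise DataError("n_monomers must be >= 1")
    return mae / n_monomers


def display_round(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the convention used for displayed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP)) * (
        -1.0 if x < 0 else 1.0
    )


@dataclass
class FitResult:
    """Optimized scaling factors with the objective curve and per-size statistics."""

    scaling: ScalingFactors
    objective_value: float  # pooled MAE at the optimum, kcal/mol
    curve: list[tuple[float, float]] = field(default_factory=list)
    per_size_stats: dict[int, ErrorStats] = field(default_factory=dict)
    flat_flag: bool = False
    mode: str = "s8_only"
    n_iterations: int = 0


Record = tuple[DeviationRecord, DispersionComponents]


def pair_records(
    devs: Sequence[DeviationRecord], comps: Sequence[DispersionComponents]
) -> list[Record]:
    """Match deviation records with dispersion components by structure id."""
    by_id = {c.structure_id: c for c in comps}
    out = []
    for d in devs:
        if d.structure_id not in by_id:
            raise DataError(f"no dispersion components for structure {d.structure_id!r}")
        out.append((d, by_id[d.structure_id]))
    return out


def _arrays(records: Sequence[Record]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not records:
        raise DataError("cannot fit on an empty record set")
    d = np.array([r.deviation for r, _ in records])
    e6 = np.array([c.e6_raw for _, c in records])
    e8 = np.array([c.e8_raw for _, c in records])
    return d, e6, e8


def _mae_curve(d, e6, e8, s6, s8_values) -> np.ndarray:
    resid = d - s6 * e6
    return np.mean(np.abs(resid[None, :] - np.outer(s8_values, e8)), axis=1)


def _exact_1d_min(
    resid: np.ndarray,
    coeff: np.ndarray,
    bounds: tuple[float, float],
    objective: str = "mae",
):
    """Exact minimizer of the chosen objective of (resid − s·coeff) over bounds.

    For "mae" the objective is convex piecewise-linear and the minimum is
    attained at a breakpoint resid_i/coeff_i or at a bound; ties resolve to
    the smallest s. For "mse" the minimizer is the least-squares closed form,
    clipped to the bounds. Returns (s, objective_value, flat) with flat=True
    when no coefficient is nonzero.
    """
    lo, hi = bounds
    if lo > hi:
        raise DataError(f"empty bounds interval ({lo}, {hi})")
    if objective not in ("mae", "mse"):
        raise DataError(f"unknown objective {objective!r}")
    nz = coeff != 0.0
    if not np.any(nz):
        val = np.abs(resid) if objective == "mae" else resid**2
        return lo, float(np.mean(val)), True
    if objective == "mse":
        s = float(np.clip(np.dot(resid, coeff) / np.dot(coeff, coeff), lo, hi))
        return s, float(np.mean((resid - s * coeff) ** 2)), False
    candidates = np.clip(resid[nz] / coeff[nz], lo, hi)
    candidates = np.unique(np.concatenate([candidates, [lo, hi]]))
    values = np.mean(np.abs(resid[None, :] - np.outer(candidates, coeff)), axis=1)
    best = np.min(values)
    # smallest s among (near-)ties
    s = float(candidates[np.argmax(values <= best + 1e-15)])
    return s, float(best), False


def _finish(
    records: Sequence[Record],
    scaling: ScalingFactors,
    objective: float,
    curve_bounds: tuple[float, float],
    flat: bool,
    mode: str,
    n_iter: int,
    curve_points: int,
) -> FitResult:
    d, e6, e8 = _arrays(records)
    grid = np.linspace(curve_bounds[0], curve_bounds[1], curve_points)
    curve = list(zip(grid.tolist(), _mae_curve(d, e6, e8, scaling.s6, grid).tolist()))
    per_size: dict[int, ErrorStats] = {}
    for size in sorted({r.n_monomers for r, _ in records}):
        subset = [
            apply_dispersion(r, c, scaling)
            for r, c in records
            if r.n_monomers == size
        ]
        per_size[size] = error_stats(subset)
    return FitResult(scaling, objective, curve, per_size, flat, mode, n_iter)


def optimize_s8(
    records: Sequence[Record],
    s6_fixed: float = 1.0,
    bounds: tuple[float, float] = (0.0, 5.0),
    curve_points: int = 101,
    objective: str = "mae",
) -> FitResult:
    """Exact minimization over S8 with S6 held fixed (MAE by default).

    When every e8 component vanishes the objective is flat in S8; the lower
    bound is returned with ``flat_flag`` set rather than failing, since a
    flat objective is a legitimate (if degenerate) outcome. ``objective="mse"``
    switches to the least-squares closed form (sensitivity analysis).
    """
    d, e6, e8 = _arrays(records)
    s8, obj, flat = _exact_1d_min(d - s6_fixed * e6, e8, bounds, objective)
    return _finish(
        records, ScalingFactors(s6_fixed, s8), obj, bounds, flat, "s8_only", 1, curve_points
    )


def _lp_polish(d, e6, e8, s6_bounds, s8_bounds):
    """Exact global L1 fit via linear programming (HiGHS)."""
    n = len(d)
    c = np.concatenate([[0.0, 0.0], np.ones(n) / n])
    eye = np.eye(n)
    a_ub = np.block(
        [[-e6[:, None], -e8[:, None], -eye], [e6[:, None], e8[:, None], -eye]]
    )
    b_ub = np.concatenate([-d, d])
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[s6_bounds, s8_bounds] + [(0, None)] * n,
        method="highs",
    )
    if not res.success:  # pragma: no cover - HiGHS is robust on feasible LPs
        return None
    return float(res.x[0]), float(res.x[1]), float(res.fun)


def optimize_s6_s8(
    records: Sequence[Record],
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 2.0), (0.0, 5.0)),
    mode: str = "joint",
    s6_fixed: float = 1.0,
    max_iterations: int = 100,
    curve_points: int = 101,
    objective: str = "mae",
) -> FitResult:
    """Optimize the scaling factors in one of three modes.

    ``"s8_only"`` fixes S6 = ``s6_fixed``; ``"s6_only_s8_zero"`` pins S8 = 0
    and refits S6 alone (the minimal-correction refit used when the n=8 term
    is removed altogether); ``"joint"`` alternates exact 1-D minimizations
    until the objective improves by < 1e-10, then applies an exact LP polish.
    """
    s6_bounds, s8_bounds = bounds
    d, e6, e8 = _arrays(records)
    if mode == "s8_only":
        return optimize_s8(records, s6_fixed, s8_bounds, curve_points, objective)
    if mode == "s6_only_s8_zero":
        s6, obj, flat = _exact_1d_min(d, e6, s6_bounds, objective)
        return _finish(
            records, ScalingFactors(s6, 0.0), obj, s8_bounds, flat, mode, 1, curve_points
        )
    if mode != "joint":
        raise DataError(f"unknown fit mode {mode!r}")

    s6 = min(max(1.0, s6_bounds[0]), s6_bounds[1])
    prev = math.inf
    obj = float(np.mean(np.abs(d - s6 * e6)))  # refreshed on the first pass
    s8 = s8_bounds[0]
    flat6 = flat8 = False
    it = 0
    for it in range(1, max_iterations + 1):
        s8, obj, flat8 = _exact_1d_min(d - s6 * e6, e8, s8_bounds, objective)
        s6, obj, flat6 = _exact_1d_min(d - s8 * e8, e6, s6_bounds, objective)
        if prev - obj < 1e-10:
            break
        prev = obj
    if objective == "mae":
        # coordinate descent on a polyhedral objective can stall at a vertex
        # optimal per axis but not jointly; the LP finds the true minimum
        polished = _lp_polish(d, e6, e8, s6_bounds, s8_bounds)
        if polished is not None and polished[2] < obj - 1e-12:
            s6, s8, obj = polished
            # re-run one exact coordinate pass so the factors sit on breakpoints
            s8, obj, flat8 = _exact_1d_min(d - s6 * e6, e8, s8_bounds)
            s6, obj, flat6 = _exact_1d_min(d - s8 * e8, e6, s6_bounds)
    return _finish(
        records,
        ScalingFactors(s6, s8),
        obj,
        s8_bounds,
        flat6 and flat8,
        "joint",
        it,
        curve_points,
    )


def scan_s8(
    records: Sequence[Record], s6_fixed: float, grid: Sequence[float]
) -> list[tuple[float, float]]:
    """MAE at each grid value of S8, via the linear decomposition."""
    if len(grid) == 0:
        raise DataError("scan grid must be non-empty")
    d, e6, e8 = _arrays(records)
    values = _mae_curve(d, e6, e8, s6_fixed, np.asarray(grid, dtype=float))
    return list(zip([float(g) for g in grid], values.tolist()))


# --------------------------------------------------------------- reports ---

_TABLE_COLUMNS = [
    "cluster_size",
    "model",
    "err_kcal_mol",
    "mse_kcal2_mol2",
    "mae_kcal_mol",
    "mae_per_molecule_kcal_mol",
]


def report_tables(
    stats_by_model_and_size: Mapping[str, Mapping[int, ErrorStats]],
    tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Emit the standard deviation-statistics table layout.

    The TSV shows 2-decimal display rounding (half away from zero); the JSON
    carries full precision. The dispersion energy here follows the convention
    that E_dis is positive and subtracted from the electronic energy.
    """
    rows = []
    payload: dict[str, dict[str, dict]] = {}
    for model, by_size in stats_by_model_and_size.items():
        payload[model] = {}
        for size in sorted(by_size):
            st = by_size[size]
            payload[model][str(size)] = {
                "err": st.err,
                "mse": st.mse,
                "mae": st.mae,
                "mae_per_mol": st.mae_per_mol,
                "n_configs": st.n_configs,
                "n_monomers": st.n_monomers,
            }
            rows.append(
                {
                    "cluster_size": size,
                    "model": model,
                    "err_kcal_mol": f"{display_round(st.err):.2f}",
                    "mse_kcal2_mol2": f"{display_round(st.mse):.2f}",
                    "mae_kcal_mol": f"{display_round(st.mae):.2f}",
                    "mae_per_molecule_kcal_mol": f"{display_round(st.mae_per_mol):.2f}",
                }
            )
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    if tsv_path is not None:
        Path(tsv_path).write_text(df.to_csv(sep="\t", index=False))
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    return df, payload
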