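"""Deterministic sensitivity analyses: one-way (tornado), two-way, threshold.

All sweeps re-evaluate both strategies with the swept parameter(s) pinned
and everything else at base values. The headline bar metric for the tornado
is the span of the incremental net monetary benefit (comparator minus
reference) at the willingness-to-pay threshold across the parameter's
range: unlike the raw ICER it is stable when incremental QALYs pass through
zero. ICERs at both ends are emitted alongside.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .engine import evaluate_cohort, evaluate_cohort_batch
from .model import StrategyModel
from .parameters import ParameterSet

__all__ = [
    "OneWayResult",
    "TwoWayResult",
    "one_way",
    "tornado",
    "threshold_search",
    "two_way",
    "NoCrossingError",
    "tornado_plot",
    "two_way_plot",
]

_COST_KINDS = {"cost", "toll_cost"}


def _pair(models: Sequence[StrategyModel]) -> tuple[StrategyModel, StrategyModel]:
    if len(models) != 2:
        raise ValueError("expected exactly two strategies (reference, comparator)")
    return models[0], models[1]


def _inc_nmb(models, params: ParameterSet, wtp: float) -> tuple[float, float | None]:
    """Incremental NMB (comparator - reference) and ICER at given inputs."""
    ref_m, cmp_m = _pair(models)
    ref = evaluate_cohort(ref_m, params, want_trace=False)
    cmp_ = evaluate_cohort(cmp_m, params, want_trace=False)
    d_cost = cmp_.total_cost - ref.total_cost
    d_qaly = cmp_.total_qaly - ref.total_qaly
    ratio = d_cost / d_qaly if d_qaly != 0 else None
    return wtp * d_qaly - d_cost, ratio


@dataclass(frozen=True)
class OneWayResult:
    """Comparative outcome with one parameter pinned at its range ends."""

    key: str
    low: float
    high: float
    nmb_diff_low: float
    nmb_diff_high: float
    icer_low: float | None
    icer_high: float | None
    wtp: float

    @property
    def width(self) -> float:
        """Tornado bar width: span of the incremental NMB across the range."""
        return abs(self.nmb_diff_high - self.nmb_diff_low)


def one_way(
    models: Sequence[StrategyModel],
    params: ParameterSet,
    key: str,
    wtp: float | None = None,
) -> OneWayResult:
    """Pin ``key`` at its low then high value and record the comparison.

    A degenerate range (low == high) yields a zero-width bar.
    """
    p = params[key]
    wtp = params.wtp if wtp is None else wtp
    nmb_lo, icer_lo = _inc_nmb(models, params.with_overrides({key: p.low}), wtp)
    nmb_hi, icer_hi = _inc_nmb(models, params.with_overrides({key: p.high}), wtp)
    return OneWayResult(
        key=key, low=p.low, high=p.high,
        nmb_diff_low=nmb_lo, nmb_diff_high=nmb_hi,
        icer_low=icer_lo, icer_high=icer_hi, wtp=wtp,
    )


def tornado(
    models: Sequence[StrategyModel],
    params: ParameterSet,
    keys: Sequence[str] | None = None,
    wtp: float | None = None,
) -> pd.DataFrame:
    """One-way sweeps for every non-fixed parameter, sorted by bar width.

    Returns one row per parameter with the incremental-NMB span (bar width),
    incremental NMB and ICER at each end, and a 1-based rank.
    """
    wtp = params.wtp if wtp is None else wtp
    if keys is None:
        keys = [k for k in sorted(params.keys()) if not params[k].is_fixed]
    rows = []
    for key in keys:
        r = one_way(models, params, key, wtp=wtp)
        rows.append(
            {
                "key": key,
                "low": r.low,
                "high": r.high,
                "nmb_diff_low": r.nmb_diff_low,
                "nmb_diff_high": r.nmb_diff_high,
                "icer_low": r.icer_low,
                "icer_high": r.icer_high,
                "width": r.width,
            }
        )
    frame = pd.DataFrame(rows).sort_values("width", ascending=False, kind="mergesort")
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame.reset_index(drop=True)


class NoCrossingError(ValueError):
    """The decision does not flip between the given bounds."""


def threshold_search(
    models: Sequence[StrategyModel],
    params: ParameterSet,
    key: str,
    bounds: tuple[float, float],
    wtp: float | None = None,
    tol: float | None = None,
) -> float:
    """Parameter value at which the NMB-optimal strategy flips.

    Bisection (Brent) on the incremental NMB as a function of the parameter
    over ``bounds``; requires a sign change (i.e. the cost-effective
    strategy differs at the two ends). Default tolerance: $1 for costs,
    1e-4 for probabilities and utilities.
    """
    wtp = params.wtp if wtp is None else wtp
    p = params[key]
    if tol is None:
        tol = 1.0 if p.kind in _COST_KINDS else 1e-4
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError(f"bounds must satisfy lo < hi, got {bounds}")

    def g(x: float) -> float:
        nmb, _ = _inc_nmb(models, params.with_overrides({key: x}), wtp)
        return nmb

    g_lo, g_hi = g(lo), g(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if np.sign(g_lo) == np.sign(g_hi):
        raise NoCrossingError(
            f"{key}: incremental NMB has the same sign at both bounds "
            f"({g_lo:.1f} at {lo}, {g_hi:.1f} at {hi}); no decision flip to locate"
        )
    return float(brentq(g, lo, hi, xtol=tol))


@dataclass
class TwoWayResult:
    """Cost-effective strategy over a grid of two parameters."""

    key_x: str
    key_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    decision: np.ndarray  # (len(y_values), len(x_values)) of strategy names
    wtp: float

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x_values, self.y_values)
        return pd.DataFrame(
            {
                self.key_x: xx.ravel(),
                self.key_y: yy.ravel(),
                "decision": self.decision.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def two_way(
    models: Sequence[StrategyModel],
    params: ParameterSet,
    key_x: str,
    key_y: str,
    n_x: int = 101,
    n_y: int = 101,
    wtp: float | None = None,
) -> TwoWayResult:
    """Decision map at the WTP threshold over the Cartesian [low, high] grid."""
    ref_m, cmp_m = _pair(models)
    wtp = params.wtp if wtp is None else wtp
    px, py = params[key_x], params[key_y]
    x_values = np.linspace(px.low, px.high, n_x)
    y_values = np.linspace(py.low, py.high, n_y)
    xx, yy = np.meshgrid(x_values, y_values)

    key_order = tuple(sorted(params.keys()))
    kidx = {k: i for i, k in enumerate(key_order)}
    base = np.array([params.value(k) for k in key_order])
    values = np.tile(base, (xx.size, 1))
    values[:, kidx[key_x]] = xx.ravel()
    values[:, kidx[key_y]] = yy.ravel()

    ref_cost, ref_qaly = evaluate_cohort_batch(ref_m, params, values, key_order)
    cmp_cost, cmp_qaly = evaluate_cohort_batch(cmp_m, params, values, key_order)
    inc_nmb = wtp * (cmp_qaly - ref_qaly) - (cmp_cost - ref_cost)
    decision = np.where(inc_nmb > 0, cmp_m.name, ref_m.name).reshape(xx.shape)
    return TwoWayResult(
        key_x=key_x, key_y=key_y, x_values=x_values, y_values=y_values,
        decision=decision, wtp=wtp,
    )


# ---------------------------------------------------------------------------
# Plots (publication-style artifacts; backend-free Figure objects)
# ---------------------------------------------------------------------------


def tornado_plot(frame: pd.DataFrame, path: str | Path, top: int = 15) -> None:
    """Horizontal tornado bars of incremental-NMB spans (widest on top)."""
    from matplotlib.figure import Figure

    sub = frame.head(top).iloc[::-1]
    fig = Figure(figsize=(8, 0.4 * len(sub) + 1.5))
    ax = fig.add_subplot()
    lo = np.minimum(sub["nmb_diff_low"], sub["nmb_diff_high"])
    hi = np.maximum(sub["nmb_diff_low"], sub["nmb_diff_high"])
    ax.barh(sub["key"], hi - lo, left=lo, color="#4878d0")
    ax.set_xlabel("Incremental NMB (comparator - reference), $")
    ax.axvline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def two_way_plot(result: TwoWayResult, path: str | Path) -> None:
    """Filled decision-region map over the two-parameter grid."""
    from matplotlib.colors import ListedColormap
    from matplotlib.figure import Figure
    from matplotlib.patches import Patch

    names = sorted(np.unique(result.decision))
    codes = np.searchsorted(names, result.decision)
    colors = ["#1f77b4", "#ff7f0e", "#2ca02c"][: len(names)]
    fig = Figure(figsize=(6.5, 5))
    ax = fig.add_subplot()
    ax.pcolormesh(result.x_values, result.y_values, codes,
                  cmap=ListedColormap(colors), shading="auto")
    ax.set_xlabel(result.key_x)
    ax.set_ylabel(result.key_y)
    ax.legend(handles=[Patch(color=c, label=n) for c, n in zip(colors, names)],
              loc="upper right", title=f"Cost-effective at ${result.wtp:,.0f}/QALY")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
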