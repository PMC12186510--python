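"""Probabilistic sensitivity analysis (PSA).

Every non-fixed parameter is drawn independently from its fitted
distribution — beta for probabilities, utilities and disutility tolls,
gamma for costs — and both strategies are re-evaluated with the
deterministic cohort solver once per draw (one expected-value evaluation
per Monte Carlo simulation). Outputs: draw-level incremental cost and
effectiveness, cost-effectiveness acceptability curves (CEAC), and the 95%
confidence ellipse on the incremental cost-effectiveness plane.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import evaluate_cohort_batch
from .model import StrategyModel
from .parameters import ParameterError, ParameterSet

__all__ = [
    "PsaResult",
    "run_psa",
    "ceac",
    "Ellipse",
    "confidence_ellipse",
    "scatter_plot",
    "ceac_plot",
    "DEFAULT_WTP_GRID",
]

#: default CEAC grid: $0 to $250 000 in $5 000 steps
DEFAULT_WTP_GRID = np.arange(0, 250_001, 5_000, dtype=float)


@dataclass
class PsaResult:
    """Joint parameter draws and per-draw strategy outcomes.

    ``samples`` has one row per draw: per-strategy (cost, qaly) plus the
    incremental pair (comparator minus reference). ``parameter_draws``
    holds the sampled values of every non-fixed parameter.
    """

    reference: str
    comparator: str
    samples: pd.DataFrame
    parameter_draws: pd.DataFrame
    n: int
    seed: int
    horizon_years: float
    wtp: float

    def incremental(self) -> tuple[np.ndarray, np.ndarray]:
        """(d_qaly, d_cost) arrays, comparator minus reference."""
        return self.samples["d_qaly"].to_numpy(), self.samples["d_cost"].to_numpy()

    def acceptability(self, wtp: float | None = None) -> dict[str, float]:
        """Fraction of draws in which each strategy has maximal NMB (ties split)."""
        wtp = self.wtp if wtp is None else wtp
        d_qaly, d_cost = self.incremental()
        inc_nmb = wtp * d_qaly - d_cost
        frac_cmp = float(np.mean(inc_nmb > 0) + 0.5 * np.mean(inc_nmb == 0))
        return {self.comparator: frac_cmp, self.reference: 1.0 - frac_cmp}

    def to_csv(self, path: str | Path) -> None:
        self.samples.to_csv(path, index=False)


def _sample_values(
    params: ParameterSet, n: int, rng: np.random.Generator, key_order: tuple[str, ...]
) -> np.ndarray:
    values = np.tile([params.value(k) for k in key_order], (n, 1))
    for j, key in enumerate(key_order):
        p = params[key]
        if p.is_fixed:
            continue
        try:
            dist = p.fitted()
        except ParameterError as exc:
            raise ParameterError(f"{key}: infeasible distribution fit ({exc})") from exc
        values[:, j] = dist.rvs(size=n, random_state=rng)
    return values


def run_psa(
    models: Sequence[StrategyModel],
    params: ParameterSet,
    n: int,
    seed: int,
    keep_parameter_draws: bool = True,
) -> PsaResult:
    """Joint Monte Carlo over all non-fixed parameters, ``n`` draws.

    Each draw samples every non-fixed parameter independently from its
    fitted beta/gamma distribution and evaluates both strategies with the
    cohort solver. Seeded and bit-reproducible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(models) != 2:
        raise ValueError("expected exactly two strategies (reference, comparator)")
    ref_m, cmp_m = models
    rng = np.random.default_rng(seed)
    key_order = tuple(sorted(params.keys()))
    values = _sample_values(params, n, rng, key_order)

    ref_cost, ref_qaly = evaluate_cohort_batch(ref_m, params, values, key_order)
    cmp_cost, cmp_qaly = evaluate_cohort_batch(cmp_m, params, values, key_order)
    samples = pd.DataFrame(
        {
            "draw": np.arange(n),
            f"cost_{ref_m.name}": ref_cost,
            f"qaly_{ref_m.name}": ref_qaly,
            f"cost_{cmp_m.name}": cmp_cost,
            f"qaly_{cmp_m.name}": cmp_qaly,
            "d_cost": cmp_cost - ref_cost,
            "d_qaly": cmp_qaly - ref_qaly,
        }
    )
    sampled_cols = [k for k in key_order if not params[k].is_fixed]
    draws = pd.DataFrame(
        values[:, [key_order.index(k) for k in sampled_cols]], columns=sampled_cols
    ) if keep_parameter_draws else pd.DataFrame(index=range(n))
    return PsaResult(
        reference=ref_m.name,
        comparator=cmp_m.name,
        samples=samples,
        parameter_draws=draws,
        n=n,
        seed=seed,
        horizon_years=params.horizon_years,
        wtp=params.wtp,
    )


def ceac(result: PsaResult, wtp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each WTP value, the fraction of draws in which each strategy attains
    the maximal net monetary benefit (exact ties split equally). Fractions
    sum to 1 at every grid point.
    """
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty WTP grid")
    if result.samples.empty:
        raise ValueError("no PSA samples")
    d_qaly, d_cost = result.incremental()
    inc_nmb = wtp_grid[:, None] * d_qaly[None, :] - d_cost[None, :]
    frac_cmp = (inc_nmb > 0).mean(axis=1) + 0.5 * (inc_nmb == 0).mean(axis=1)
    return pd.DataFrame(
        {"wtp": wtp_grid, result.comparator: frac_cmp, result.reference: 1.0 - frac_cmp}
    )


@dataclass(frozen=True)
class Ellipse:
    """Confidence ellipse on the (d_qaly, d_cost) plane."""

    center: tuple[float, float]  # (d_qaly, d_cost)
    semi_axes: tuple[float, float]  # major, minor
    angle_deg: float  # orientation of the major axis, counterclockwise from +x
    level: float
    degenerate: bool


def confidence_ellipse(result: PsaResult, level: float = 0.95) -> Ellipse:
    """Bivariate-normal confidence ellipse for the incremental outcomes.

    Centre at the sample mean of (d_qaly, d_cost); axes along the covariance
    eigenvectors with semi-axis lengths ``sqrt(eigval * chi2.ppf(level, 2))``.
    Identity covariance at level 0.95 gives both semi-axes
    ``sqrt(5.991) = 2.4477``.
    """
    d_qaly, d_cost = result.incremental()
    if d_qaly.size < 3:
        raise ValueError("need at least 3 samples for a covariance ellipse")
    xy = np.column_stack([d_qaly, d_cost])
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    eigval, eigvec = np.linalg.eigh(cov)
    degenerate = bool(eigval.min() <= 1e-300 * max(eigval.max(), 1.0))
    eigval = np.clip(eigval, 0.0, None)
    scale = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(eigval * scale)
    # eigh sorts ascending: index 1 is the major axis
    major_vec = eigvec[:, 1]
    angle = float(np.degrees(np.arctan2(major_vec[1], major_vec[0])) % 180.0)
    return Ellipse(
        center=(float(center[0]), float(center[1])),
        semi_axes=(float(semi[1]), float(semi[0])),
        angle_deg=angle,
        level=level,
        degenerate=degenerate,
    )


def scatter_plot(result: PsaResult, path: str | Path, level: float = 0.95) -> None:
    """Incremental cost-effectiveness scatter, colored by cost-effectiveness
    at the WTP threshold, with the confidence ellipse and WTP line."""
    from matplotlib.figure import Figure
    from matplotlib.patches import Ellipse as MplEllipse

    d_qaly, d_cost = result.incremental()
    ce = result.wtp * d_qaly - d_cost > 0
    fig = Figure(figsize=(6.5, 5.5))
    ax = fig.add_subplot()
    ax.scatter(d_qaly[~ce], d_cost[~ce], s=3, alpha=0.3, color="#1f77b4",
               label=f"{result.reference} cost-effective")
    ax.scatter(d_qaly[ce], d_cost[ce], s=3, alpha=0.3, color="#ff7f0e",
               label=f"{result.comparator} cost-effective")
    ell = confidence_ellipse(result, level)
    if not ell.degenerate:
        ax.add_patch(
            MplEllipse(ell.center, 2 * ell.semi_axes[0], 2 * ell.semi_axes[1],
                       angle=ell.angle_deg, fill=False, color="k", lw=1.5)
        )
    lim = np.array(ax.get_xlim())
    ax.plot(lim, result.wtp * lim, "k--", lw=0.8,
            label=f"WTP ${result.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)
    ax.set_xlabel(f"Incremental QALYs ({result.comparator} - {result.reference})")
    ax.set_ylabel("Incremental cost, $")
    ax.legend(loc="lower right", markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def ceac_plot(curves: pd.DataFrame, path: str | Path) -> None:
    """Acceptability curves: P(cost-effective) against willingness to pay."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6.5, 4.5))
    ax = fig.add_subplot()
    for col in curves.columns:
        if col != "wtp":
            ax.plot(curves["wtp"], curves[col], label=col)
    ax.set_xlabel("Willingness to pay, $/QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
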