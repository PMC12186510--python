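"""Evaluation engine: deterministic cohort solver and individual microsimulation.

Accrual convention: state membership at the start of a 3-month cycle earns
that state's full per-cycle cost and utility, valued at the cycle-start
discount time (no half-cycle correction by default; an optional flag
averages start- and end-of-cycle occupancy instead). One-time tolls fire on
the transition into a state, at the destination cycle's discount time; the
entry state's tolls (initial treatment) fire at model entry only. The death
state accrues nothing.

The cohort solver iterates an occupancy vector; the batch variant evaluates
many parameter draws simultaneously (used by the probabilistic sensitivity
analysis) and the microsimulation samples individual trajectories from the
same per-cycle transition matrices, so the three agree by construction up
to Monte Carlo error.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import json
import numpy as np
import pandas as pd

from .model import StrategyModel, validate_model
from .parameters import ParameterSet

__all__ = [
    "discount_factor",
    "evaluate_cohort",
    "evaluate_cohort_batch",
    "simulate_individuals",
    "EvaluationResult",
    "MicrosimResult",
    "ModelValidationError",
]


class ModelValidationError(ValueError):
    """Raised when a model/parameter pair fails validation before evaluation."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("model validation failed:\n  " + "\n  ".join(violations))


def discount_factor(t_years: float, rate: float) -> float:
    """Present-value factor ``(1 + rate) ** (-t_years)`` with annual compounding."""
    if t_years < 0:
        raise ValueError(f"t_years must be >= 0, got {t_years}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    return float((1.0 + rate) ** (-t_years))


# ---------------------------------------------------------------------------
# Compiled strategy: index-based view of a model bound to a parameter ordering
# ---------------------------------------------------------------------------


@dataclass
class _CompiledStrategy:
    model: StrategyModel
    key_order: tuple[str, ...]
    state_names: tuple[str, ...]
    entry_idx: int
    # per-rule arrays
    r_from: np.ndarray
    r_to: np.ndarray
    r_key: np.ndarray
    r_arr: np.ndarray  # risk-reduction key index, -1 when absent
    r_exponent: np.ndarray  # p_cycle = 1 - (1-p) ** exponent
    r_start: np.ndarray
    r_stop: np.ndarray
    # per-state accrual term lists
    util_terms: list[tuple[int, list[tuple[int, float]]]]
    cost_terms: list[list[tuple[int, float]]]
    tollcost_terms: list[list[tuple[int, float]]]
    tolldis_terms: list[list[tuple[int, float]]]


_BASIS_YEARS = {"per_year": 1.0, "at_5_years": 5.0}


def _compile(model: StrategyModel, params: ParameterSet) -> _CompiledStrategy:
    violations = validate_model(model, params)
    if violations:
        raise ModelValidationError(violations)
    key_order = tuple(sorted(params.keys()))
    kidx = {k: i for i, k in enumerate(key_order)}
    names = model.state_names
    sidx = {n: i for i, n in enumerate(names)}
    cl = params.cycle_length_years

    r_from, r_to, r_key, r_arr, r_exp, r_start, r_stop = [], [], [], [], [], [], []
    for r in model.rules:
        p = params[r.prob_key]
        r_from.append(sidx[r.from_state])
        r_to.append(sidx[r.to_state])
        r_key.append(kidx[r.prob_key])
        r_arr.append(-1 if r.risk_reduction_key is None else kidx[r.risk_reduction_key])
        basis = _BASIS_YEARS.get(p.time_basis)
        r_exp.append(1.0 if basis is None else cl / basis)
        start, stop = r.window if r.window is not None else (0, np.iinfo(np.int64).max)
        r_start.append(start)
        r_stop.append(stop)

    util_terms, cost_terms, tollc, tolld = [], [], [], []
    for s in model.states:
        u = (-1, []) if s.utility_key is None else (
            kidx[s.utility_key],
            [(kidx[k], w) for k, w in s.disutility_keys],
        )
        util_terms.append(u)
        cost_terms.append([(kidx[k], w) for k, w in s.cost_keys])
        tc, td = [], []
        for k in s.entry_toll_keys:
            (tc if params[k].kind == "toll_cost" else td).append((kidx[k], 1.0))
        tollc.append(tc)
        tolld.append(td)

    return _CompiledStrategy(
        model=model,
        key_order=key_order,
        state_names=names,
        entry_idx=sidx[model.entry_state],
        r_from=np.asarray(r_from),
        r_to=np.asarray(r_to),
        r_key=np.asarray(r_key),
        r_arr=np.asarray(r_arr),
        r_exponent=np.asarray(r_exp),
        r_start=np.asarray(r_start),
        r_stop=np.asarray(r_stop),
        util_terms=util_terms,
        cost_terms=cost_terms,
        tollcost_terms=tollc,
        tolldis_terms=tolld,
    )


def _accrual_arrays(cs: _CompiledStrategy, values: np.ndarray):
    """Per-state utility/cost/toll arrays of shape (B, S) from values (B, P)."""
    B = values.shape[0]
    S = len(cs.state_names)
    util = np.zeros((B, S))
    cost = np.zeros((B, S))
    toll_cost = np.zeros((B, S))
    toll_dis = np.zeros((B, S))
    for s in range(S):
        u_idx, dis = cs.util_terms[s]
        if u_idx >= 0:
            u = values[:, u_idx].copy()
            for d_idx, w in dis:
                u -= w * values[:, d_idx]
            util[:, s] = np.clip(u, 0.0, 1.0)
        for c_idx, w in cs.cost_terms[s]:
            cost[:, s] += w * values[:, c_idx]
        for c_idx, w in cs.tollcost_terms[s]:
            toll_cost[:, s] += w * values[:, c_idx]
        for d_idx, w in cs.tolldis_terms[s]:
            toll_dis[:, s] += w * values[:, d_idx]
    return util, cost, toll_cost, toll_dis


def _rule_cycle_probs(cs: _CompiledStrategy, values: np.ndarray) -> np.ndarray:
    """Per-cycle probability of each rule, shape (B, R)."""
    p = values[:, cs.r_key].copy()
    mod = cs.r_arr >= 0
    if mod.any():
        p[:, mod] = np.clip(p[:, mod] - values[:, cs.r_arr[mod]], 0.0, 1.0)
    p = np.clip(p, 0.0, 1.0)
    return 1.0 - (1.0 - p) ** cs.r_exponent


def _matrix_for_mask(cs: _CompiledStrategy, p_cycle: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Transition matrices (B, S, S) for the rule-activity mask of one regime."""
    B = p_cycle.shape[0]
    S = len(cs.state_names)
    P = np.zeros((B, S, S))
    for i in np.flatnonzero(mask):
        P[:, cs.r_from[i], cs.r_to[i]] += p_cycle[:, i]
    rowsum = P.sum(axis=2)
    # degenerate draws can push a row above 1: rescale outgoing mass
    over = rowsum > 1.0
    if over.any():
        scale = np.where(over, rowsum, 1.0)
        P /= scale[:, :, None]
        rowsum = np.minimum(rowsum, 1.0)
    stay = 1.0 - rowsum
    idx = np.arange(S)
    P[:, idx, idx] += stay
    return P


def _cycle_signatures(cs: _CompiledStrategy, n_cycles: int):
    """Group cycles by which windowed rules are active."""
    sig_for_cycle = []
    cache: dict[tuple, int] = {}
    masks: list[np.ndarray] = []
    for k in range(n_cycles):
        mask = (cs.r_start <= k) & (k < cs.r_stop)
        key = tuple(mask)
        if key not in cache:
            cache[key] = len(masks)
            masks.append(mask)
        sig_for_cycle.append(cache[key])
    return sig_for_cycle, masks


def _base_values(cs: _CompiledStrategy, params: ParameterSet) -> np.ndarray:
    return np.array([[params.value(k) for k in cs.key_order]])


def _run_cohort(
    cs: _CompiledStrategy,
    params: ParameterSet,
    values: np.ndarray,
    half_cycle_correction: bool = False,
    want_trace: bool = False,
):
    n_cycles = params.n_cycles
    cl = params.cycle_length_years
    rate = params.discount_rate
    B = values.shape[0]
    S = len(cs.state_names)

    util, cost, toll_cost, toll_dis = _accrual_arrays(cs, values)
    p_cycle = _rule_cycle_probs(cs, values)
    sig_for_cycle, masks = _cycle_signatures(cs, n_cycles)
    matrices = [_matrix_for_mask(cs, p_cycle, m) for m in masks]
    diag_idx = np.arange(S)

    occ = np.zeros((B, S))
    occ[:, cs.entry_idx] = 1.0
    inflow = np.zeros((B, S))
    inflow[:, cs.entry_idx] = 1.0

    total_cost = np.zeros(B)
    total_qaly = np.zeros(B)
    trace_rows = [] if want_trace else None

    for k in range(n_cycles):
        df = discount_factor(k * cl, rate)
        P = matrices[sig_for_cycle[k]]
        occ_end = np.einsum("bf,bfs->bs", occ, P)
        occ_acc = 0.5 * (occ + occ_end) if half_cycle_correction else occ
        cycle_cost = (occ_acc * cost).sum(axis=1) + (inflow * toll_cost).sum(axis=1)
        cycle_qaly = (occ_acc * util).sum(axis=1) * cl - (inflow * toll_dis).sum(axis=1)
        total_cost += df * cycle_cost
        total_qaly += df * cycle_qaly
        if want_trace:
            trace_rows.append(
                {
                    "cycle": k,
                    "time_years": k * cl,
                    "discount": df,
                    "cycle_cost": float(cycle_cost[0]),
                    "cycle_qaly": float(cycle_qaly[0]),
                    "disc_cycle_cost": float(df * cycle_cost[0]),
                    "disc_cycle_qaly": float(df * cycle_qaly[0]),
                    **{f"occ_{n}": float(occ[0, i]) for i, n in enumerate(cs.state_names)},
                }
            )
        inflow = occ_end - occ * P[:, diag_idx, diag_idx]
        # re-entries into the entry state never refire initial-treatment tolls
        inflow[:, cs.entry_idx] = 0.0
        np.clip(inflow, 0.0, None, out=inflow)
        occ = occ_end

    trace = pd.DataFrame(trace_rows) if want_trace else None
    return total_cost, total_qaly, trace


# ---------------------------------------------------------------------------
# Public results and entry points
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    """Discounted totals for one strategy, with the per-cycle cohort trace."""

    strategy: str
    total_cost: float
    total_qaly: float
    horizon_years: float
    discount_rate: float
    trace: pd.DataFrame | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(
            {
                "strategy": self.strategy,
                "total_cost": self.total_cost,
                "total_qaly": self.total_qaly,
                "horizon_years": self.horizon_years,
                "discount_rate": self.discount_rate,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    def trace_tidy(self) -> pd.DataFrame:
        """Long-format trace: one row per (cycle, state) with occupancy."""
        if self.trace is None:
            raise ValueError("result carries no trace")
        occ_cols = [c for c in self.trace.columns if c.startswith("occ_")]
        long = self.trace.melt(
            id_vars=["cycle", "time_years", "discount", "cycle_cost", "cycle_qaly",
                     "disc_cycle_cost", "disc_cycle_qaly"],
            value_vars=occ_cols,
            var_name="state",
            value_name="occupancy",
        )
        long["state"] = long["state"].str.removeprefix("occ_")
        return long

    def trace_to_csv(self, path: str | Path) -> None:
        self.trace_tidy().to_csv(path, index=False)


def evaluate_cohort(
    model: StrategyModel,
    params: ParameterSet,
    half_cycle_correction: bool = False,
    want_trace: bool = True,
) -> EvaluationResult:
    """Deterministic expected-value evaluation of one strategy.

    Iterates the cohort occupancy vector over ``horizon / cycle_length``
    cycles from the entry state, accruing discounted costs and
    quality-adjusted life-years as described in the module docstring.
    """
    cs = _compile(model, params)
    cost, qaly, trace = _run_cohort(
        cs, params, _base_values(cs, params),
        half_cycle_correction=half_cycle_correction, want_trace=want_trace,
    )
    return EvaluationResult(
        strategy=model.name,
        total_cost=float(cost[0]),
        total_qaly=float(qaly[0]),
        horizon_years=params.horizon_years,
        discount_rate=params.discount_rate,
        trace=trace,
    )


def evaluate_cohort_batch(
    model: StrategyModel,
    params: ParameterSet,
    values: np.ndarray,
    key_order: tuple[str, ...] | None = None,
    half_cycle_correction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cohort evaluation over many parameter-value draws.

    ``values`` has one row per draw and one column per parameter in
    ``key_order`` (default: sorted parameter keys). Returns
    ``(total_costs, total_qalys)`` arrays of length ``values.shape[0]``.
    """
    cs = _compile(model, params)
    if key_order is not None and tuple(key_order) != cs.key_order:
        order = {k: i for i, k in enumerate(key_order)}
        values = values[:, [order[k] for k in cs.key_order]]
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(cs.key_order):
        raise ValueError(
            f"values must be (n_draws, {len(cs.key_order)}), got {values.shape}"
        )
    cost, qaly, _ = _run_cohort(
        cs, params, values, half_cycle_correction=half_cycle_correction, want_trace=False
    )
    return cost, qaly


@dataclass
class MicrosimResult:
    """Per-individual discounted (cost, QALY) pairs from microsimulation."""

    strategy: str
    costs: np.ndarray
    qalys: np.ndarray
    n: int
    seed: int

    @property
    def mean_cost(self) -> float:
        return float(self.costs.mean())

    @property
    def mean_qaly(self) -> float:
        return float(self.qalys.mean())

    @property
    def se_cost(self) -> float:
        return float(self.costs.std(ddof=1) / np.sqrt(self.n)) if self.n > 1 else 0.0

    @property
    def se_qaly(self) -> float:
        return float(self.qalys.std(ddof=1) / np.sqrt(self.n)) if self.n > 1 else 0.0


def simulate_individuals(
    model: StrategyModel, params: ParameterSet, n: int, seed: int
) -> MicrosimResult:
    """Individual-level Monte Carlo simulation of ``n`` trajectories.

    Transitions are sampled categorically per cycle from the same per-cycle
    matrices the cohort solver uses; accrual and discounting rules are
    identical, so means converge to :func:`evaluate_cohort` totals by the
    law of large numbers. Identical seeds give bit-identical results.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cs = _compile(model, params)
    values = _base_values(cs, params)
    util, cost, toll_cost, toll_dis = (a[0] for a in _accrual_arrays(cs, values))
    p_cycle = _rule_cycle_probs(cs, values)
    n_cycles = params.n_cycles
    cl = params.cycle_length_years
    sig_for_cycle, masks = _cycle_signatures(cs, n_cycles)
    cum_matrices = []
    for m in masks:
        P = _matrix_for_mask(cs, p_cycle, m)[0]
        cum = np.cumsum(P, axis=1)
        cum[:, -1] = 1.0
        cum_matrices.append(cum)

    rng = np.random.default_rng(seed)
    states = np.full(n, cs.entry_idx, dtype=np.int64)
    costs = np.full(n, toll_cost[cs.entry_idx])  # initial-treatment toll at entry
    qalys = np.full(n, -toll_dis[cs.entry_idx])

    for k in range(n_cycles):
        df = discount_factor(k * cl, params.discount_rate)
        if k > 0:
            # arrival tolls for transitions made at the end of the previous cycle
            arrived = states != prev_states
            arrived &= states != cs.entry_idx  # entry tolls fire at model entry only
            if arrived.any():
                costs[arrived] += df * toll_cost[states[arrived]]
                qalys[arrived] -= df * toll_dis[states[arrived]]
        costs += df * cost[states]
        qalys += df * util[states] * cl
        cum = cum_matrices[sig_for_cycle[k]]
        u = rng.random(n)
        prev_states = states
        states = (u[:, None] >= cum[states]).sum(axis=1)

    return MicrosimResult(strategy=model.name, costs=costs, qalys=qalys, n=n, seed=seed)
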