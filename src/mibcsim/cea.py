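"""Comparative cost-effectiveness statistics: ICER, NMB, decision tables.

Sign conventions: increments are comparator minus reference. A comparator
that costs more and yields fewer QALYs is *dominated*; cheaper and more
effective is *dominant*. When incremental QALYs are zero the ICER is
undefined and the comparison degenerates to cost minimisation. The
cost-effective strategy at a willingness-to-pay (WTP) threshold is the one
with maximal net monetary benefit, NMB = WTP * QALY - cost.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import math
import pandas as pd

from .engine import EvaluationResult

__all__ = ["net_monetary_benefit", "icer", "IcerRow", "CeaTable", "efficiency_frontier"]


def net_monetary_benefit(result: EvaluationResult, wtp: float) -> float:
    """``wtp * qaly - cost`` in USD; higher is better."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * result.total_qaly - result.total_cost


@dataclass(frozen=True)
class IcerRow:
    """One comparator-versus-reference comparison."""

    reference: str
    comparator: str
    d_cost: float
    d_qaly: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "cost_minimization"
    wtp: float
    decision: str  # strategy with maximal NMB at wtp

    @property
    def comparator_cost_effective(self) -> bool:
        return self.decision == self.comparator


def icer(
    reference: EvaluationResult, comparator: EvaluationResult, wtp: float = 100_000.0
) -> IcerRow:
    """Incremental cost-effectiveness of ``comparator`` versus ``reference``."""
    d_cost = comparator.total_cost - reference.total_cost
    d_qaly = comparator.total_qaly - reference.total_qaly
    if d_qaly == 0.0:
        ratio, label = None, "cost_minimization"
    else:
        ratio = d_cost / d_qaly
        if d_cost <= 0.0 and d_qaly > 0.0:
            label = "dominant"
        elif d_cost >= 0.0 and d_qaly < 0.0:
            label = "dominated"
        else:
            label = "icer"
    nmb_ref = net_monetary_benefit(reference, wtp)
    nmb_cmp = net_monetary_benefit(comparator, wtp)
    if nmb_cmp > nmb_ref:
        decision = comparator.strategy
    elif nmb_cmp < nmb_ref:
        decision = reference.strategy
    else:
        decision = "tie"
    return IcerRow(
        reference=reference.strategy,
        comparator=comparator.strategy,
        d_cost=d_cost,
        d_qaly=d_qaly,
        icer=ratio,
        label=label,
        wtp=wtp,
        decision=decision,
    )


def efficiency_frontier(results: list[EvaluationResult]) -> list[EvaluationResult]:
    """Non-dominated frontier for k strategies (strict and extended dominance).

    Sort by cost; drop strategies that are strictly dominated (another costs
    less with at least as many QALYs) and extended-dominated (a convex
    combination of two others beats them). With exactly two strategies this
    is a no-op unless one strictly dominates.
    """
    ordered = sorted(results, key=lambda r: (r.total_cost, -r.total_qaly))
    frontier: list[EvaluationResult] = []
    for r in ordered:
        if frontier and r.total_qaly <= frontier[-1].total_qaly:
            continue  # strictly dominated
        frontier.append(r)
    # extended dominance: successive ICERs must increase along the frontier
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = (mid.total_cost - lo.total_cost) / (mid.total_qaly - lo.total_qaly)
            icer_hi = (hi.total_cost - mid.total_cost) / (hi.total_qaly - mid.total_qaly)
            if icer_lo >= icer_hi:
                frontier.pop(i)
                changed = True
                break
    return frontier


@dataclass
class CeaTable:
    """Base-case decision table for a set of strategies at one horizon."""

    results: list[EvaluationResult]
    wtp: float
    reference: str

    @classmethod
    def from_results(
        cls, results: list[EvaluationResult], wtp: float = 100_000.0, reference: str | None = None
    ) -> "CeaTable":
        if not results:
            raise ValueError("no results")
        if reference is None:
            reference = min(results, key=lambda r: r.total_cost).strategy
        if reference not in {r.strategy for r in results}:
            raise ValueError(f"reference {reference!r} not among results")
        return cls(results=list(results), wtp=wtp, reference=reference)

    @property
    def decision(self) -> str:
        """Strategy with maximal net monetary benefit at the table's WTP."""
        return max(self.results, key=lambda r: net_monetary_benefit(r, self.wtp)).strategy

    def rows(self) -> list[IcerRow]:
        ref = next(r for r in self.results if r.strategy == self.reference)
        return [icer(ref, r, self.wtp) for r in self.results if r.strategy != self.reference]

    def to_frame(self) -> pd.DataFrame:
        ref = next(r for r in self.results if r.strategy == self.reference)
        records = []
        for r in self.results:
            if r.strategy == self.reference:
                records.append(
                    {
                        "strategy": r.strategy,
                        "cost": r.total_cost,
                        "qaly": r.total_qaly,
                        "d_cost": 0.0,
                        "d_qaly": 0.0,
                        "icer": None,
                        "label": "reference",
                        "nmb": net_monetary_benefit(r, self.wtp),
                    }
                )
            else:
                row = icer(ref, r, self.wtp)
                records.append(
                    {
                        "strategy": r.strategy,
                        "cost": r.total_cost,
                        "qaly": r.total_qaly,
                        "d_cost": row.d_cost,
                        "d_qaly": row.d_qaly,
                        "icer": row.icer,
                        "label": row.label,
                        "nmb": net_monetary_benefit(r, self.wtp),
                    }
                )
        frame = pd.DataFrame(records)
        frame["cost_effective"] = frame["strategy"] == self.decision
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [f"{'Strategy':<22}{'Cost, $':>12}{'QALY':>8}  ICER, $/QALY"]
        for rec in self.to_frame().to_dict(orient="records"):
            if rec["label"] == "reference":
                icer_txt = "1 [Reference]"
            elif rec["icer"] is None or not math.isfinite(rec["icer"]):
                icer_txt = rec["label"]
            elif rec["label"] != "icer":
                icer_txt = rec["label"]
            else:
                icer_txt = f"{rec['icer']:,.0f}"
            lines.append(
                f"{rec['strategy']:<22}{rec['cost']:>12,.0f}{rec['qaly']:>8.2f}  {icer_txt}"
            )
        lines.append(
            f"Cost-effective at ${self.wtp:,.0f}/QALY: {self.decision}"
        )
        return "\n".join(lines)
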