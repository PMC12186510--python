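"""Model inputs: parameters, validation, time-scale conversion, PSA distributions.

A decision model of this kind is driven by three families of inputs —
transition probabilities, per-cycle / one-time costs (2021 USD, payer
perspective) and health-state utilities with one-time disutility tolls.
Each input carries a base value plus a low/high uncertainty range and a
probabilistic-sensitivity-analysis distribution family: beta for
probabilities and utilities (support [0, 1]), gamma for costs
(support [0, inf)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterError",
    "read_parameters",
    "to_cycle_probability",
    "fit_beta",
    "fit_gamma",
]

KINDS = ("probability", "cost", "utility", "toll_disutility", "toll_cost")
TIME_BASES = ("per_cycle", "per_year", "at_5_years")
DISTRIBUTIONS = ("beta", "gamma", "fixed")

#: kinds whose values live on [0, 1] and draw from a beta distribution
_UNIT_KINDS = frozenset({"probability", "utility", "toll_disutility"})
#: kinds whose values are nonnegative dollar amounts and draw from a gamma
_COST_KINDS = frozenset({"cost", "toll_cost"})

_BASIS_YEARS = {"per_year": 1.0, "at_5_years": 5.0}

# Range-to-standard-error convention: treat [low, high] as a 95% interval.
_RANGE_Z = 2.0 * 1.959963984540054


class ParameterError(ValueError):
    """Raised for malformed or inconsistent model inputs."""


def to_cycle_probability(p: float, basis: str, cycle_length_years: float) -> float:
    """Convert a probability stated on ``basis`` to a per-cycle probability.

    Conversion assumes a constant hazard over the stated interval:
    ``p_cycle = 1 - (1 - p) ** (cycle_length / basis_years)``. A
    ``per_cycle`` basis passes through unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability {p!r} outside [0, 1]")
    if cycle_length_years <= 0:
        raise ParameterError("cycle_length_years must be positive")
    if basis == "per_cycle":
        return float(p)
    try:
        basis_years = _BASIS_YEARS[basis]
    except KeyError:
        raise ParameterError(f"unknown time basis {basis!r}") from None
    if p == 1.0:
        return 1.0
    return float(1.0 - (1.0 - p) ** (cycle_length_years / basis_years))


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters for a given mean and SE.

    ``nu = mean*(1-mean)/se**2 - 1``; ``alpha = mean*nu``; ``beta = (1-mean)*nu``.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must lie strictly in (0, 1), got {mean}")
    if se <= 0:
        raise ParameterError("beta se must be positive")
    if se * se >= mean * (1.0 - mean):
        raise ParameterError(
            f"infeasible beta variance: se^2={se * se:.6g} >= mean*(1-mean)={mean * (1 - mean):.6g}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments (shape, scale) of a gamma with given mean and SE."""
    if mean <= 0 or se <= 0:
        raise ParameterError("gamma mean and se must be positive")
    return (mean / se) ** 2, se * se / mean


@dataclass(frozen=True)
class Parameter:
    """One model input with base value, uncertainty range and PSA distribution."""

    key: str
    kind: str
    base: float
    low: float
    high: float
    time_basis: str = "per_cycle"
    distribution: str = "fixed"
    note: str = ""

    def validate(self) -> list[str]:
        """Return human-readable invariant violations (empty when valid)."""
        v: list[str] = []
        k = self.key
        if self.kind not in KINDS:
            v.append(f"{k}: unknown kind {self.kind!r}")
            return v
        if self.time_basis not in TIME_BASES:
            v.append(f"{k}: unknown time_basis {self.time_basis!r}")
        if self.distribution not in DISTRIBUTIONS:
            v.append(f"{k}: unknown distribution {self.distribution!r}")
            return v
        if not self.low <= self.base <= self.high:
            v.append(f"{k}: base {self.base} outside [low, high] = [{self.low}, {self.high}]")
        if self.kind in _UNIT_KINDS:
            for name, val in (("low", self.low), ("base", self.base), ("high", self.high)):
                if not 0.0 <= val <= 1.0:
                    v.append(f"{k}: {self.kind} {name} {val} outside [0, 1]")
            if self.distribution == "gamma":
                v.append(f"{k}: {self.kind} parameters use beta or fixed distributions, not gamma")
        elif self.kind in _COST_KINDS:
            for name, val in (("low", self.low), ("base", self.base), ("high", self.high)):
                if val < 0:
                    v.append(f"{k}: {self.kind} {name} {val} is negative")
            if self.distribution == "beta":
                v.append(f"{k}: {self.kind} parameters use gamma or fixed distributions, not beta")
        if self.kind != "probability" and self.time_basis != "per_cycle":
            v.append(f"{k}: time_basis {self.time_basis!r} only applies to probabilities")
        return v

    @property
    def is_fixed(self) -> bool:
        """Fixed parameters (degenerate range or fixed tag) are excluded from PSA."""
        return self.distribution == "fixed" or self.low == self.high

    @property
    def se(self) -> float:
        """Standard error implied by the range, read as a 95% interval."""
        return (self.high - self.low) / _RANGE_Z

    def fitted(self):
        """Frozen scipy distribution for PSA draws, or ``None`` when fixed."""
        if self.is_fixed:
            return None
        se = self.se
        if self.kind in _UNIT_KINDS:
            # utilities of exactly 0 or 1 are nudged to keep the moments feasible
            mean = min(max(self.base, 1e-6), 1.0 - 1e-6)
            a, b = fit_beta(mean, se)
            return stats.beta(a, b)
        shape, scale = fit_gamma(max(self.base, 1e-9), se)
        return stats.gamma(shape, scale=scale)

    def cycle_probability(self, cycle_length_years: float) -> float:
        if self.kind != "probability":
            raise ParameterError(f"{self.key}: not a probability")
        return to_cycle_probability(self.base, self.time_basis, cycle_length_years)


_SETTING_FIELDS = ("discount_rate", "wtp", "cycle_length_years", "horizon_years")


@dataclass
class ParameterSet:
    """All model inputs plus the run settings they are evaluated under."""

    entries: dict[str, Parameter] = field(default_factory=dict)
    discount_rate: float = 0.03
    wtp: float = 100_000.0
    cycle_length_years: float = 0.25
    horizon_years: float = 5.0

    # -- mapping-ish access -------------------------------------------------
    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> Parameter:
        try:
            return self.entries[key]
        except KeyError:
            raise ParameterError(f"unknown parameter key {key!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def keys(self):
        return self.entries.keys()

    def value(self, key: str) -> float:
        return self[key].base

    # -- derived ------------------------------------------------------------
    @property
    def n_cycles(self) -> int:
        n = self.horizon_years / self.cycle_length_years
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"horizon {self.horizon_years} y is not a whole number of "
                f"{self.cycle_length_years} y cycles"
            )
        return int(round(n))

    def cycle_probability(self, key: str) -> float:
        return self[key].cycle_probability(self.cycle_length_years)

    def validate(self) -> list[str]:
        v: list[str] = []
        for p in self.entries.values():
            v.extend(p.validate())
        if self.discount_rate < 0:
            v.append(f"discount_rate {self.discount_rate} is negative")
        if self.wtp <= 0:
            v.append(f"wtp {self.wtp} must be positive")
        if self.cycle_length_years <= 0:
            v.append("cycle_length_years must be positive")
        if self.horizon_years <= 0:
            v.append("horizon_years must be positive")
        return v

    # -- functional updates ---------------------------------------------------
    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """New ParameterSet with selected base values replaced."""
        entries = dict(self.entries)
        for key, base in overrides.items():
            p = self[key]
            entries[key] = replace(
                p, base=float(base), low=min(p.low, float(base)), high=max(p.high, float(base))
            )
        return replace(self, entries=entries)

    def with_settings(self, **settings: float) -> "ParameterSet":
        unknown = set(settings) - set(_SETTING_FIELDS)
        if unknown:
            raise ParameterError(f"unknown settings {sorted(unknown)}")
        return replace(self, **settings)

    # -- I/O ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "key": p.key,
                "kind": p.kind,
                "base": p.base,
                "low": p.low,
                "high": p.high,
                "time_basis": p.time_basis,
                "distribution": p.distribution,
                "note": p.note,
            }
            for p in self.entries.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "settings": {f: float(getattr(self, f)) for f in _SETTING_FIELDS},
            "parameters": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_REQUIRED_COLUMNS = ("key", "kind", "base", "low", "high", "time_basis", "distribution")


def _build_set(records: Iterable[Mapping], settings: Mapping | None = None) -> ParameterSet:
    entries: dict[str, Parameter] = {}
    errors: list[str] = []
    for i, row in enumerate(records):
        missing = [c for c in _REQUIRED_COLUMNS if c not in row or pd.isna(row[c])]
        if missing:
            errors.append(f"row {i}: missing field(s) {missing}")
            continue
        try:
            p = Parameter(
                key=str(row["key"]),
                kind=str(row["kind"]),
                base=float(row["base"]),
                low=float(row["low"]),
                high=float(row["high"]),
                time_basis=str(row["time_basis"]),
                distribution=str(row["distribution"]),
                note="" if pd.isna(row.get("note", "")) else str(row.get("note", "")),
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
            continue
        if p.key in entries:
            errors.append(f"row {i}: duplicate key {p.key!r}")
            continue
        errors.extend(p.validate())
        entries[p.key] = p
    if errors:
        raise ParameterError("; ".join(errors))
    ps = ParameterSet(entries=entries)
    if settings:
        ps = ps.with_settings(**{k: float(v) for k, v in settings.items()})
    return ps


def read_parameters(path: str | Path, format: str | None = None) -> ParameterSet:
    """Read a ParameterSet from the CSV or YAML parameter-table schema."""
    path = Path(path)
    if format is None:
        format = "yaml" if path.suffix.lower() in {".yaml", ".yml"} else "csv"
    if format == "csv":
        frame = pd.read_csv(path)
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ParameterError(f"{path}: missing column(s) {missing}")
        return _build_set(frame.to_dict(orient="records"))
    if format == "yaml":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict) or "parameters" not in doc:
            raise ParameterError(f"{path}: expected a mapping with a 'parameters' list")
        return _build_set(doc["parameters"], doc.get("settings"))
    raise ParameterError(f"unknown format {format!r}")
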