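"""Strategy-specific health-state graphs for the two treatment arms.

Two strategies for muscle-invasive bladder cancer (MIBC) are modelled:

* **TMT** (trimodal therapy: maximal transurethral resection +
  radiosensitizing chemotherapy + radiotherapy) — bladder-preserving, so the
  arm tracks intravesical recurrences. MIBC recurrence is treated with
  salvage radical cystectomy, NMIBC recurrence with induction BCG,
  metastatic progression with gemcitabine/cisplatin, and progression on
  first-line therapy with pembrolizumab.
* **RC** (radical cystectomy with urinary diversion) — no bladder remains,
  so there are no intravesical recurrence states; long-term toxicity
  decomposes into bowel obstruction, parastomal hernia and uretero-enteric
  anastomotic complication categories.

States accrue a per-cycle cost and utility while occupied; one-time tolls
(costs and utility decrements) fire on entry. Transition rules reference
parameter keys; the residual probability mass in each row is the stay
probability, and death is the unique absorbing state.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from .parameters import ParameterSet, to_cycle_probability

__all__ = [
    "HealthState",
    "TransitionRule",
    "StrategyModel",
    "build_tmt_model",
    "build_rc_model",
    "validate_model",
    "RC_LONG_TERM_CATEGORIES",
]

#: tracked complication categories behind the RC long-term toxicity state
RC_LONG_TERM_CATEGORIES = (
    "bowel_obstruction",
    "parastomal_hernia",
    "ureteroenteric_stricture",
)


@dataclass(frozen=True)
class HealthState:
    """One node of a strategy's state graph.

    ``utility_key`` resolves to the state's per-cycle utility; entries of
    ``disutility_keys`` (key, weight) are subtracted from it, which is how
    the RC long-term toxicity state composes its three complication
    categories. ``cost_keys`` (key, weight) sum to the per-cycle cost.
    ``entry_toll_keys`` are one-time costs / disutilities fired on entering
    the state (on the entry state they fire at model entry only).
    """

    name: str
    utility_key: str | None = None
    disutility_keys: tuple[tuple[str, float], ...] = ()
    cost_keys: tuple[tuple[str, float], ...] = ()
    entry_toll_keys: tuple[str, ...] = ()
    absorbing: bool = False


@dataclass(frozen=True)
class TransitionRule:
    """A per-cycle transition ``from_state -> to_state`` with probability
    ``prob_key``.

    ``window`` restricts the rule to cycles ``start <= k < stop`` (``None``
    means always active) — used for treatment-phase toxicity. Parallel rules
    between the same pair of states add. ``risk_reduction_key`` names an
    absolute risk reduction subtracted from the probability on its stated
    time basis before per-cycle conversion (used for the TMT
    metastasis-risk-reduction lever).
    """

    from_state: str
    to_state: str
    prob_key: str
    window: tuple[int, int] | None = None
    risk_reduction_key: str | None = None


@dataclass(frozen=True)
class StrategyModel:
    """A named strategy: states, transition rules and entry state."""

    name: str
    states: tuple[HealthState, ...]
    rules: tuple[TransitionRule, ...]
    entry_state: str
    cycle_length_years: float = 0.25
    treatment_map: dict[str, str] = field(default_factory=dict)
    long_term_categories: tuple[str, ...] = ()

    def state(self, name: str) -> HealthState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(f"{self.name}: no state named {name!r}")

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def absorbing_states(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states if s.absorbing)

    def rules_from(self, name: str) -> tuple[TransitionRule, ...]:
        return tuple(r for r in self.rules if r.from_state == name)

    def graph(self) -> nx.DiGraph:
        """Transition-structure digraph (self-loops for residual mass included)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.state_names)
        for r in self.rules:
            g.add_edge(r.from_state, r.to_state, prob_key=r.prob_key)
        for s in self.states:
            g.add_edge(s.name, s.name)  # residual stay mass
        return g

    def stay_probability(self, name: str, params: ParameterSet, cycle: int = 0) -> float:
        """Residual self-loop probability of a state at a given cycle."""
        out = 0.0
        for r in self.rules_from(name):
            if r.window is not None and not (r.window[0] <= cycle < r.window[1]):
                continue
            out += resolve_cycle_probability(r, params)
        return 1.0 - out

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "entry_state": self.entry_state,
            "cycle_length_years": self.cycle_length_years,
            "treatment_map": dict(self.treatment_map),
            "long_term_categories": list(self.long_term_categories),
            "states": [
                {
                    "name": s.name,
                    "utility_key": s.utility_key,
                    "disutility_keys": [list(x) for x in s.disutility_keys],
                    "cost_keys": [list(x) for x in s.cost_keys],
                    "entry_toll_keys": list(s.entry_toll_keys),
                    "absorbing": s.absorbing,
                }
                for s in self.states
            ],
            "rules": [
                {
                    "from_state": r.from_state,
                    "to_state": r.to_state,
                    "prob_key": r.prob_key,
                    "window": list(r.window) if r.window else None,
                    "risk_reduction_key": r.risk_reduction_key,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "StrategyModel":
        states = tuple(
            HealthState(
                name=s["name"],
                utility_key=s.get("utility_key"),
                disutility_keys=tuple((k, float(w)) for k, w in s.get("disutility_keys", [])),
                cost_keys=tuple((k, float(w)) for k, w in s.get("cost_keys", [])),
                entry_toll_keys=tuple(s.get("entry_toll_keys", [])),
                absorbing=bool(s.get("absorbing", False)),
            )
            for s in doc["states"]
        )
        rules = tuple(
            TransitionRule(
                from_state=r["from_state"],
                to_state=r["to_state"],
                prob_key=r["prob_key"],
                window=tuple(r["window"]) if r.get("window") else None,
                risk_reduction_key=r.get("risk_reduction_key"),
            )
            for r in doc["rules"]
        )
        return cls(
            name=doc["name"],
            states=states,
            rules=rules,
            entry_state=doc["entry_state"],
            cycle_length_years=float(doc.get("cycle_length_years", 0.25)),
            treatment_map=dict(doc.get("treatment_map", {})),
            long_term_categories=tuple(doc.get("long_term_categories", ())),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StrategyModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dot(self) -> str:
        """Graphviz DOT rendering of the state graph (for documentation)."""
        lines = [f'digraph "{self.name}" {{', "  rankdir=LR;"]
        for s in self.states:
            shape = "doublecircle" if s.absorbing else "ellipse"
            lines.append(f'  "{s.name}" [shape={shape}];')
        for r in self.rules:
            label = r.prob_key
            if r.window:
                label += f" [cycles {r.window[0]}..{r.window[1] - 1}]"
            lines.append(f'  "{r.from_state}" -> "{r.to_state}" [label="{label}"];')
        lines.append("}")
        return "\n".join(lines)


def resolve_cycle_probability(rule: TransitionRule, params: ParameterSet) -> float:
    """Per-cycle probability of a rule at base parameter values.

    The optional absolute risk reduction is applied on the probability's own
    time basis (e.g. a 5-year cumulative scale) before constant-hazard
    conversion to the cycle length.
    """
    p = params[rule.prob_key]
    value = p.base
    if rule.risk_reduction_key is not None:
        value = min(max(value - params[rule.risk_reduction_key].base, 0.0), 1.0)
    return to_cycle_probability(value, p.time_basis, params.cycle_length_years)


# ---------------------------------------------------------------------------
# Model constructors
# ---------------------------------------------------------------------------

# Shared metastatic-pathway states: first-line gemcitabine/cisplatin, second
# line pembrolizumab; the TMT arm additionally tracks a terminal
# (best-supportive-care) state after second-line progression.
_M1 = HealthState(
    "metastatic_first_line",
    utility_key="u_metastatic",
    cost_keys=(("c_gc_chemotherapy", 1.0),),
)
_M2 = HealthState(
    "metastatic_second_line",
    utility_key="u_mets_second_line",
    cost_keys=(("c_pembrolizumab", 1.0),),
)
_DEATH = HealthState("death", absorbing=True)


def build_tmt_model() -> StrategyModel:
    """Trimodal-therapy arm: nine states including bladder-recurrence states.

    The initial TMT treatment cost fires once at model entry. Short-term
    treatment toxicity is a tunnel reachable during the radiation course and
    recovery (first 3 cycles). MIBC recurrence routes into a persistent
    post-salvage-cystectomy state that carries the RC initial cost as an
    entry toll and RC-like surveillance thereafter.
    """
    states = (
        HealthState(
            "no_progression",
            utility_key="u_tmt_no_progression",
            cost_keys=(("c_tmt_surveillance", 1.0),),
            entry_toll_keys=("c_tmt_initial",),
        ),
        HealthState(
            "short_term_toxicity",
            utility_key="u_tmt_no_progression",
            disutility_keys=(("d_tmt_acute_toxicity", 1.0),),
            cost_keys=(("c_tmt_acute_toxicity", 1.0),),
        ),
        HealthState(
            "long_term_gu_gi_toxicity",
            utility_key="u_tmt_no_progression",
            disutility_keys=(("d_tmt_late_gu_gi", 1.0),),
            cost_keys=(("c_tmt_surveillance", 1.0), ("c_tmt_late_toxicity", 1.0)),
        ),
        HealthState(
            "recurrent_nmibc",
            utility_key="u_nmibc_recurrence",
            cost_keys=(("c_nmibc_treatment", 1.0),),
            entry_toll_keys=("c_bcg_induction", "t_nmibc_disutility"),
        ),
        HealthState(
            # post-salvage-cystectomy: RC-like surveillance with the RC
            # initial cost fired as a one-time toll on entry
            "recurrent_mibc",
            utility_key="u_rc_no_progression",
            cost_keys=(("c_rc_surveillance", 1.0),),
            entry_toll_keys=("c_rc_initial", "t_salvage_cystectomy_disutility"),
        ),
        _M1,
        _M2,
        HealthState(
            "metastatic_terminal",
            utility_key="u_terminal",
            cost_keys=(("c_terminal_care", 1.0),),
        ),
        _DEATH,
    )
    arr = "tmt_metastasis_arr_5y"
    rules = (
        TransitionRule("no_progression", "short_term_toxicity", "p_tmt_acute_toxicity", window=(0, 3)),
        TransitionRule("no_progression", "long_term_gu_gi_toxicity", "p_tmt_late_toxicity"),
        TransitionRule("no_progression", "recurrent_nmibc", "p_nmibc_recurrence"),
        TransitionRule("no_progression", "recurrent_mibc", "p_mibc_recurrence"),
        TransitionRule("no_progression", "metastatic_first_line", "p_metastasis", risk_reduction_key=arr),
        TransitionRule("no_progression", "death", "p_other_cause_death"),
        TransitionRule("short_term_toxicity", "no_progression", "p_acute_toxicity_resolution"),
        TransitionRule("short_term_toxicity", "death", "p_other_cause_death"),
        TransitionRule("long_term_gu_gi_toxicity", "metastatic_first_line", "p_metastasis", risk_reduction_key=arr),
        TransitionRule("long_term_gu_gi_toxicity", "death", "p_other_cause_death"),
        TransitionRule("recurrent_nmibc", "no_progression", "p_nmibc_resolution"),
        TransitionRule("recurrent_nmibc", "recurrent_mibc", "p_nmibc_to_mibc"),
        TransitionRule("recurrent_nmibc", "metastatic_first_line", "p_metastasis", risk_reduction_key=arr),
        TransitionRule("recurrent_nmibc", "death", "p_other_cause_death"),
        TransitionRule("recurrent_mibc", "metastatic_first_line", "p_metastasis", risk_reduction_key=arr),
        TransitionRule("recurrent_mibc", "death", "p_other_cause_death"),
        TransitionRule("metastatic_first_line", "metastatic_second_line", "p_mets_progression_first_line"),
        TransitionRule("metastatic_first_line", "death", "p_mets_death_first_line"),
        TransitionRule("metastatic_second_line", "metastatic_terminal", "p_mets_progression_second_line"),
        TransitionRule("metastatic_second_line", "death", "p_mets_death_second_line"),
        TransitionRule("metastatic_terminal", "death", "p_terminal_death"),
    )
    return StrategyModel(
        name="TMT",
        states=states,
        rules=rules,
        entry_state="no_progression",
        treatment_map={
            "metastasis": "gemcitabine_cisplatin",
            "recurrent_mibc": "salvage_radical_cystectomy",
            "recurrent_nmibc": "bcg_induction",
            "second_metastatic_progression": "pembrolizumab",
        },
    )


def build_rc_model() -> StrategyModel:
    """Radical-cystectomy arm: six states, no intravesical recurrence states.

    Perioperative toxicity is reachable in the first 2 cycles only. The
    long-term toxicity state composes three tracked complication categories
    (equal mix) for both its per-cycle disutility and cost. Progression on
    second-line therapy is not tracked as a separate state; its hazard adds
    to the second-line exit-to-death rule.
    """
    states = (
        HealthState(
            "no_progression",
            utility_key="u_rc_no_progression",
            cost_keys=(("c_rc_surveillance", 1.0),),
            entry_toll_keys=("c_rc_initial",),
        ),
        HealthState(
            "short_term_toxicity",
            utility_key="u_rc_no_progression",
            disutility_keys=(("d_rc_periop_toxicity", 1.0),),
            cost_keys=(("c_rc_periop_toxicity", 1.0),),
        ),
        HealthState(
            "long_term_toxicity",
            utility_key="u_rc_no_progression",
            disutility_keys=tuple((f"d_{c}", 1.0 / 3.0) for c in RC_LONG_TERM_CATEGORIES),
            cost_keys=(("c_rc_surveillance", 1.0),)
            + tuple((f"c_{c}", 1.0 / 3.0) for c in RC_LONG_TERM_CATEGORIES),
            entry_toll_keys=("t_rc_late_toxicity_cost",),
        ),
        _M1,
        _M2,
        _DEATH,
    )
    rules = (
        TransitionRule("no_progression", "short_term_toxicity", "p_rc_periop_toxicity", window=(0, 2)),
        TransitionRule("no_progression", "long_term_toxicity", "p_rc_late_toxicity"),
        TransitionRule("no_progression", "metastatic_first_line", "p_metastasis"),
        TransitionRule("no_progression", "death", "p_other_cause_death"),
        TransitionRule("short_term_toxicity", "no_progression", "p_acute_toxicity_resolution"),
        TransitionRule("short_term_toxicity", "death", "p_other_cause_death"),
        TransitionRule("long_term_toxicity", "metastatic_first_line", "p_metastasis"),
        TransitionRule("long_term_toxicity", "death", "p_other_cause_death"),
        TransitionRule("metastatic_first_line", "metastatic_second_line", "p_mets_progression_first_line"),
        TransitionRule("metastatic_first_line", "death", "p_mets_death_first_line"),
        # second-line progression is not tracked separately after RC;
        # parallel rules to death add
        TransitionRule("metastatic_second_line", "death", "p_mets_progression_second_line"),
        TransitionRule("metastatic_second_line", "death", "p_mets_death_second_line"),
    )
    return StrategyModel(
        name="RC",
        states=states,
        rules=rules,
        entry_state="no_progression",
        treatment_map={
            "metastasis": "gemcitabine_cisplatin",
            "second_metastatic_progression": "pembrolizumab",
        },
        long_term_categories=RC_LONG_TERM_CATEGORIES,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check_key(params: ParameterSet, key: str, kinds: tuple[str, ...], where: str) -> list[str]:
    if key not in params:
        return [f"{where}: key {key!r} not in ParameterSet"]
    if params[key].kind not in kinds:
        return [
            f"{where}: key {key!r} has kind {params[key].kind!r}, expected one of {kinds}"
        ]
    return []


def validate_model(model: StrategyModel, params: ParameterSet) -> list[str]:
    """Cross-check a strategy graph against a ParameterSet.

    Returns an empty list iff every referenced key resolves with a
    compatible kind, per-state outgoing probabilities sum to <= 1 at base
    values in every cycle regime, state utilities resolve to [0, 1], the
    model is closed, exactly one absorbing state (death) exists, and death
    is reachable from every state.
    """
    v: list[str] = []
    names = set(model.state_names)
    if len(names) != len(model.states):
        v.append(f"{model.name}: duplicate state names")
    if model.entry_state not in names:
        v.append(f"{model.name}: entry state {model.entry_state!r} not declared")

    absorbing = model.absorbing_states
    if len(absorbing) != 1:
        v.append(f"{model.name}: expected exactly one absorbing state, found {list(absorbing)}")
    elif absorbing[0] != "death":
        v.append(f"{model.name}: absorbing state is {absorbing[0]!r}, expected 'death'")

    for s in model.states:
        where = f"{model.name}.{s.name}"
        if s.absorbing:
            if model.rules_from(s.name):
                v.append(f"{where}: absorbing state has outgoing rules")
            continue
        if not model.rules_from(s.name):
            v.append(f"{where}: non-absorbing state has no outgoing transition rule")
        if s.utility_key is None:
            v.append(f"{where}: non-absorbing state lacks a utility key")
        else:
            v.extend(_check_key(params, s.utility_key, ("utility",), where))
            if s.utility_key in params and not 0.0 <= params[s.utility_key].base <= 1.0:
                v.append(f"{where}: utility {params[s.utility_key].base} outside [0, 1]")
        for key, _w in s.disutility_keys:
            v.extend(_check_key(params, key, ("toll_disutility", "utility"), where))
        for key, _w in s.cost_keys:
            v.extend(_check_key(params, key, ("cost",), where))
        for key in s.entry_toll_keys:
            v.extend(_check_key(params, key, ("toll_cost", "toll_disutility"), where))

    windows = sorted({r.window[1] for r in model.rules if r.window} | {0})
    for r in model.rules:
        where = f"{model.name}.{r.from_state}->{r.to_state}"
        if r.from_state not in names or r.to_state not in names:
            v.append(f"{where}: references an undeclared state")
            continue
        v.extend(_check_key(params, r.prob_key, ("probability",), where))
        if r.risk_reduction_key is not None:
            v.extend(_check_key(params, r.risk_reduction_key, ("probability",), where))

    if not v:
        # outgoing mass <= 1 at base values, checked in every window regime
        probe_cycles = sorted({0, *windows, max(windows, default=0) + 1})
        for s in model.states:
            if s.absorbing:
                continue
            for k in probe_cycles:
                stay = model.stay_probability(s.name, params, cycle=k)
                if stay < -1e-12:
                    v.append(
                        f"{model.name}.{s.name}: outgoing probabilities sum to "
                        f"{1.0 - stay:.6g} > 1 at cycle {k}"
                    )
                    break
        # death reachable from everywhere
        g = model.graph()
        if "death" in names:
            reaches = {n for n in names if nx.has_path(g, n, "death")}
            for n in sorted(names - reaches):
                v.append(f"{model.name}.{n}: death not reachable")
    return v
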