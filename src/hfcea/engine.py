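"""Markov cohort engine.

Six health states on a 1-month cycle: an in-hospital state, two
post-discharge tunnel months, a stable state, and two absorbing death states
(cardiovascular / non-cardiovascular). The cohort starts fully hospitalized
(the index admission). Patients not hospitalized for three consecutive months
are stable; the vulnerable phase (hospitalized month and the two tunnel
months) carries elevated cardiovascular-death and readmission risk, and any
death there counts as cardiovascular. Background non-cardiovascular mortality
applies from the stable state only, via an age-banded life table shared by
all strategies.

To encode the late-initiation strategy (switch to sacubitril-valsartan on
first reaching the stable state, never reverting), the alive transient states
are duplicated into a pre-switch and a post-switch copy; the stable state is
always post-switch. For the two phase-independent strategies the duplication
is inert.

Accrual separates *occupancy* quantities (monthly drug/standard-care cost,
monthly utility, life-years), which are half-cycle corrected (trapezoidal)
and discounted at mid-cycle, from *event* quantities (hospitalization cost
and utility decrement per admission, index admission included), which are
dated at the start of their cycle. Medication cost does not accrue during
hospitalized months — inpatient care is covered by the per-event cost —
while utility and life-years accrue in every alive state.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import (
    MONTHS_PER_YEAR,
    InputError,
    LifeTable,
    ModelError,
    ParameterSet,
)

# Expanded state space: pre-switch transient copies, post-switch copies,
# stable, and the two absorbing states.
STATES: tuple[str, ...] = (
    "hosp_pre",
    "post1_pre",
    "post2_pre",
    "hosp_post",
    "post1_post",
    "post2_post",
    "stable",
    "cv_death",
    "noncv_death",
)
N_STATES = len(STATES)
IDX = {name: i for i, name in enumerate(STATES)}

ALIVE_STATES = STATES[:7]
HOSP_STATES = ("hosp_pre", "hosp_post")
DEAD_STATES = ("cv_death", "noncv_death")

_ALIVE_IDX = np.array([IDX[s] for s in ALIVE_STATES])
_HOSP_IDX = np.array([IDX[s] for s in HOSP_STATES])

SV = "sv"
ENA = "ena"


@dataclass(frozen=True)
class StrategySpec:
    """Maps each alive state to the active drug.

    ``enalapril`` keeps enalapril everywhere; ``sv_early`` starts
    sacubitril-valsartan from the index admission; ``sv_late`` runs enalapril
    through the pre-switch states and sacubitril-valsartan from the first
    stable month onward (post-switch states included, so later readmissions
    stay on sacubitril-valsartan).
    """

    name: str
    drug_by_state: dict[str, str]

    def drug(self, state: str) -> str:
        return self.drug_by_state[state]


def _strategy(name: str, pre: str, post: str) -> StrategySpec:
    mapping = {}
    for s in ALIVE_STATES:
        mapping[s] = pre if s.endswith("_pre") else post
    return StrategySpec(name, mapping)


ENALAPRIL = _strategy("enalapril", ENA, ENA)
SV_EARLY = _strategy("sv_early", SV, SV)
SV_LATE = _strategy("sv_late", ENA, SV)

STRATEGIES = {s.name: s for s in (ENALAPRIL, SV_EARLY, SV_LATE)}


def resolve_active_drug(strategy: StrategySpec, state: str) -> str:
    """The drug a patient in ``state`` receives under ``strategy``."""
    if state in DEAD_STATES:
        raise InputError(f"no active drug in absorbing state {state!r}")
    return strategy.drug(state)


def transition_row(
    strategy: StrategySpec,
    state: str,
    age: float,
    params: ParameterSet,
    life_table: LifeTable,
) -> np.ndarray:
    """One row of the transition matrix: probabilities of next-cycle states.

    Competing risks are additive within a cycle; the residual probability
    goes to the progression target (next tunnel state, or remaining stable).
    Death rows are identity.
    """
    row = np.zeros(N_STATES)
    if state in DEAD_STATES:
        row[IDX[state]] = 1.0
        return row

    drug = resolve_active_drug(strategy, state)
    phase = "post" if (state == "stable" or state.endswith("_post")) else "pre"
    p_cvd_early = params.value(f"p_cvd_early_{drug}")
    p_hosp_early = params.value(f"p_hosp_early_{drug}")

    if state in HOSP_STATES:
        row[IDX["cv_death"]] = p_cvd_early
        row[IDX[f"post1_{phase}"]] = 1.0 - p_cvd_early
    elif state.startswith("post1"):
        row[IDX["cv_death"]] = p_cvd_early
        row[IDX[f"hosp_{phase}"]] = p_hosp_early
        row[IDX[f"post2_{phase}"]] = 1.0 - p_cvd_early - p_hosp_early
    elif state.startswith("post2"):
        row[IDX["cv_death"]] = p_cvd_early
        row[IDX[f"hosp_{phase}"]] = p_hosp_early
        row[IDX["stable"]] = 1.0 - p_cvd_early - p_hosp_early
    elif state == "stable":
        p_cvd = params.value(f"p_cvd_late_{drug}")
        p_hosp = params.value(f"p_hosp_late_{drug}")
        p_ncd = life_table.monthly_prob(age)
        row[IDX["cv_death"]] = p_cvd
        row[IDX["noncv_death"]] = p_ncd
        row[IDX["hosp_post"]] = p_hosp  # switch (if any) happened on stabilization
        row[IDX["stable"]] = 1.0 - p_cvd - p_ncd - p_hosp
    else:  # pragma: no cover - exhaustive above
        raise InputError(f"unknown state {state!r}")

    if np.any(row < 0):
        raise ModelError(
            f"competing probabilities exceed 1 in state {state!r} "
            f"({strategy.name}, age {age})"
        )
    return row


def transition_matrix(
    strategy: StrategySpec, age: float, params: ParameterSet, life_table: LifeTable
) -> np.ndarray:
    """Full row-stochastic transition matrix at one age."""
    return np.vstack(
        [transition_row(strategy, s, age, params, life_table) for s in STATES]
    )


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy for one strategy run.

    ``occupancy`` has ``horizon+1`` rows (cycle 0 is the all-hospitalized
    initial condition); ``inflow[t]`` is the fraction newly admitted at cycle
    ``t`` (1.0 at cycle 0 for the index admission — the in-hospital state
    cannot repeat, so hospital occupancy *is* new inflow).
    """

    strategy: str
    occupancy: np.ndarray  # (horizon+1, N_STATES)
    inflow: np.ndarray  # (horizon+1,)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive_fraction(self, cycle: int) -> float:
        return float(self.occupancy[cycle, _ALIVE_IDX].sum())

    def to_frame(self, discount_annual: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "cycle", np.arange(self.horizon + 1))
        df["new_hospitalizations"] = self.inflow
        if discount_annual is not None:
            t = np.arange(self.horizon + 1)
            df["discount_factor"] = (1.0 + discount_annual) ** (-t / MONTHS_PER_YEAR)
        return df

    def to_csv(self, path: str | Path, discount_annual: float | None = None) -> None:
        self.to_frame(discount_annual).to_csv(path, index=False)


def run_cohort(
    strategy: StrategySpec, params: ParameterSet, life_table: LifeTable
) -> CohortTrace:
    """Propagate the cohort from an all-hospitalized start over the horizon.

    Age advances in whole years every 12 cycles for the life-table lookup
    (the table has annual-band resolution), so one transition matrix serves
    each model year.
    """
    horizon = params.horizon_cycles
    if horizon < 1:
        raise InputError("horizon_cycles must be >= 1")
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, IDX["hosp_pre"]] = 1.0

    matrices: dict[int, np.ndarray] = {}
    for t in range(horizon):
        age_years = int(params.start_age) + t // MONTHS_PER_YEAR
        m = matrices.get(age_years)
        if m is None:
            m = transition_matrix(strategy, age_years, params, life_table)
            matrices[age_years] = m
        occ[t + 1] = occ[t] @ m

    inflow = occ[:, _HOSP_IDX].sum(axis=1)
    return CohortTrace(strategy.name, occ, inflow)


@dataclass
class RunResult:
    """Discounted totals for one strategy, decomposed into hospitalization-
    event accruals and state-occupancy accruals (totals are the exact sums),
    with undiscounted counterparts."""

    strategy: str
    cost: float
    qaly: float
    ly: float
    cost_event: float
    cost_occupancy: float
    qaly_event: float
    qaly_occupancy: float
    cost_undiscounted: float
    qaly_undiscounted: float
    ly_undiscounted: float


def _accrual_weights(strategy: StrategySpec, params: ParameterSet):
    """Per-state monthly cost and utility vectors for occupancy accrual."""
    cost_w = np.zeros(N_STATES)
    util_w = np.zeros(N_STATES)
    for s in ALIVE_STATES:
        drug = strategy.drug(s)
        util_w[IDX[s]] = params.value(f"u_{drug}_month")
        if s not in HOSP_STATES:
            # standard care (incl. enalapril) always; sac-val price on top
            cost_w[IDX[s]] = params.cost_ena_month + (
                params.cost_sv_month if drug == SV else 0.0
            )
    return cost_w, util_w


def accrue(trace: CohortTrace, strategy: StrategySpec, params: ParameterSet) -> RunResult:
    """Discounted, half-cycle-corrected totals for one cohort trace.

    Occupancy accruals use the trapezoidal average of consecutive occupancy
    rows and a mid-cycle discount factor ``(1+r)^(-(t+0.5)/12)``; event
    accruals (per-admission cost and utility decrement) use the start-of-cycle
    factor ``(1+r)^(-t/12)``.
    """
    horizon = trace.horizon
    r = params.discount_annual
    t_occ = np.arange(horizon)
    df_occ = (1.0 + r) ** (-(t_occ + 0.5) / MONTHS_PER_YEAR)
    t_evt = np.arange(horizon + 1)
    df_evt = (1.0 + r) ** (-t_evt / MONTHS_PER_YEAR)

    mid = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])  # (horizon, N)
    cost_w, util_w = _accrual_weights(strategy, params)
    alive = mid[:, _ALIVE_IDX].sum(axis=1)

    cost_occ = float(df_occ @ (mid @ cost_w))
    qaly_occ = float(df_occ @ (mid @ util_w))
    ly = float(df_occ @ alive) / MONTHS_PER_YEAR

    cost_evt = float(df_evt @ trace.inflow) * params.cost_hosp_event
    qaly_evt = float(df_evt @ trace.inflow) * params.u_hosp_event

    cost_occ_u = float((mid @ cost_w).sum())
    qaly_occ_u = float((mid @ util_w).sum())
    n_events = float(trace.inflow.sum())

    return RunResult(
        strategy=strategy.name,
        cost=cost_occ + cost_evt,
        qaly=qaly_occ + qaly_evt,
        ly=ly,
        cost_event=cost_evt,
        cost_occupancy=cost_occ,
        qaly_event=qaly_evt,
        qaly_occupancy=qaly_occ,
        cost_undiscounted=cost_occ_u + n_events * params.cost_hosp_event,
        qaly_undiscounted=qaly_occ_u + n_events * params.u_hosp_event,
        ly_undiscounted=float(alive.sum()) / MONTHS_PER_YEAR,
    )


def run_strategy(
    strategy: StrategySpec | str, params: ParameterSet, life_table: LifeTable
) -> RunResult:
    """Convenience: run the cohort and accrue in one call."""
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    trace = run_cohort(strategy, params, life_table)
    return accrue(trace, strategy, params)
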