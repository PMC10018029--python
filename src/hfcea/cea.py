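"""Economic endpoints: incremental cost, incremental effectiveness, ICER,
net monetary benefit and willingness-to-pay verdicts."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .engine import RunResult


@dataclass(frozen=True)
class IcerResult:
    """Pairwise comparison of a comparator strategy against a reference.

    ``icer`` is ``d_cost / d_effect`` on unrounded totals and only defined
    when ``d_effect != 0``; sign patterns are classified first:
    ``dominant`` (cheaper and more effective), ``dominated`` (costlier and
    less effective), ``equivalent`` (no difference), ``undefined`` (equal
    effectiveness, different cost).
    """

    reference: str
    comparator: str
    d_cost: float
    d_effect: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "equivalent" | "undefined"


def compute_icer(reference: RunResult, comparator: RunResult) -> IcerResult:
    """ICER of ``comparator`` vs ``reference`` with dominance classification
    before any division."""
    d_cost = comparator.cost - reference.cost
    d_effect = comparator.qaly - reference.qaly
    if d_effect == 0.0:
        label = "equivalent" if d_cost == 0.0 else "undefined"
        return IcerResult(reference.strategy, comparator.strategy, d_cost, d_effect, None, label)
    if d_cost <= 0.0 and d_effect > 0.0:
        label = "dominant"
    elif d_cost >= 0.0 and d_effect < 0.0:
        label = "dominated"
    else:
        label = "icer"
    return IcerResult(
        reference.strategy,
        comparator.strategy,
        d_cost,
        d_effect,
        d_cost / d_effect,
        label,
    )


def net_monetary_benefit(result: RunResult, wtp: float) -> float:
    """``wtp * QALY - cost`` (USD). The incremental NMB changes sign exactly
    at the pairwise ICER when the QALY difference is positive."""
    if wtp < 0:
        raise ValueError("wtp must be non-negative")
    return wtp * result.qaly - result.cost


def wtp_verdict(icer: IcerResult, wtp: float) -> bool:
    """True iff the comparator is cost-effective at ``wtp``: dominant, or a
    positive-effect ICER strictly below the threshold."""
    if wtp <= 0:
        raise ValueError("wtp must be positive")
    if icer.label == "dominant":
        return True
    if icer.label == "icer" and icer.d_effect > 0:
        return icer.icer < wtp
    return False


def results_table(
    reference: RunResult, comparators: list[RunResult]
) -> pd.DataFrame:
    """Base-case results table: per strategy a total row plus the
    hospitalization-event / stable-occupancy decomposition rows, with
    incremental columns against the reference."""
    rows = []

    def add(result: RunResult, ref: RunResult | None):
        inc = {"incremental_cost": None, "incremental_qaly": None, "icer": None}
        if ref is not None:
            ic = compute_icer(ref, result)
            inc = {
                "incremental_cost": ic.d_cost,
                "incremental_qaly": ic.d_effect,
                "icer": ic.icer,
            }
        rows.append(
            {"intervention": result.strategy, "component": "total",
             "cost": result.cost, "qaly": result.qaly, "ly": result.ly, **inc}
        )
        inc_ev = inc_occ = {"incremental_cost": None, "incremental_qaly": None, "icer": None}
        if ref is not None:
            inc_ev = {"incremental_cost": result.cost_event - ref.cost_event,
                      "incremental_qaly": result.qaly_event - ref.qaly_event, "icer": None}
            inc_occ = {"incremental_cost": result.cost_occupancy - ref.cost_occupancy,
                       "incremental_qaly": result.qaly_occupancy - ref.qaly_occupancy, "icer": None}
        rows.append(
            {"intervention": result.strategy, "component": "hf_hospitalization",
             "cost": result.cost_event, "qaly": result.qaly_event, "ly": 0.0, **inc_ev}
        )
        rows.append(
            {"intervention": result.strategy, "component": "stable_state",
             "cost": result.cost_occupancy, "qaly": result.qaly_occupancy,
             "ly": result.ly, **inc_occ}
        )

    add(reference, None)
    for comp in comparators:
        add(comp, reference)
    return pd.DataFrame(rows)


def export_results(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
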