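"""Deterministic (one-way / tornado) and probabilistic sensitivity analysis.

One-way analysis re-runs the full early-initiation-vs-enalapril pipeline with
a single parameter pinned to each end of its published range, everything else
at base. The tornado orders parameters by the width of the resulting ICER
interval.

The PSA draws every parameter that carries an SD and a distribution family
(beta for probabilities and utilities — the hospitalization disutility via a
beta on its magnitude, negated; gamma for costs), runs both cohort arms per
draw, and summarises acceptability against the willingness-to-pay threshold;
the CEAC evaluates acceptability over a WTP grid and a bisection locates the
0.5-crossing. Draws are independent across parameters. Structurally invalid
draws (competing probabilities reaching one) are rejected and redrawn, with
the rejection count reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import compute_icer
from .engine import ENALAPRIL, SV_EARLY, RunResult, run_strategy
from .parameters import (
    PSA_PARAMS,
    InputError,
    LifeTable,
    ModelError,
    ParameterSet,
)

logger = logging.getLogger("hfcea")

#: CEAC reporting grid (USD/QALY).
CEAC_GRID = np.arange(0.0, 50_001.0, 100.0)


# ---------------------------------------------------------------------------
# One-way / tornado
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_low: float  # ICER with the parameter at its low input value
    icer_high: float  # ICER with the parameter at its high input value

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _base_icer(params: ParameterSet, life_table: LifeTable) -> float:
    ref = run_strategy(ENALAPRIL, params, life_table)
    comp = run_strategy(SV_EARLY, params, life_table)
    res = compute_icer(ref, comp)
    if res.icer is None:
        raise ModelError("ICER undefined under these inputs")
    return res.icer


def one_way(
    params: ParameterSet, life_table: LifeTable, parameter_name: str
) -> TornadoEntry:
    """ICER at both ends of one parameter's range, all else at base."""
    if parameter_name not in params.ranges:
        raise InputError(f"{parameter_name!r} has no one-way range")
    low, high = params.ranges[parameter_name]
    icers = [
        _base_icer(params.replace(**{parameter_name: bound}), life_table)
        for bound in (low, high)
    ]
    return TornadoEntry(parameter_name, low, high, icers[0], icers[1])


def tornado(params: ParameterSet, life_table: LifeTable) -> list[TornadoEntry]:
    """One-way entries for every ranged parameter, widest bar first."""
    entries = [one_way(params, life_table, name) for name in sorted(params.ranges)]
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low": e.low,
                "high": e.high,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "width": e.width,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def draw_parameters(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One independent Monte Carlo draw of every distributed parameter.

    Parameters without an SD/distribution (life table, start age, discount
    rate) stay at base. The hospitalization disutility is drawn on its
    magnitude and negated.
    """
    drawn: dict[str, float] = {}
    for name in PSA_PARAMS:
        if name not in params.families:
            continue
        value = float(params.distribution(name).draw(rng))
        if name == "u_hosp_event":
            value = -value
        drawn[name] = value
    return params.replace(**drawn)


@dataclass
class PsaResult:
    """All per-iteration PSA outcomes plus the headline acceptability."""

    samples: pd.DataFrame  # columns: cost_ena, qaly_ena, cost_sv, qaly_sv, d_cost, d_effect
    wtp: float
    seed: int
    n_rejected: int = 0

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def acceptability(self) -> float:
        """Fraction of draws in which early sacubitril-valsartan is
        cost-effective or dominant at the base WTP (positive incremental NMB)."""
        return float(self.acceptability_at(self.wtp))

    def acceptability_at(self, wtp: float) -> float:
        nmb = wtp * self.samples["d_effect"].values - self.samples["d_cost"].values
        return float(np.mean(nmb > 0.0))


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    n_iterations: int,
    seed: int,
    log_every: int = 1000,
) -> PsaResult:
    """Monte Carlo PSA: per iteration one parameter draw and two full cohort
    runs (early sacubitril-valsartan vs enalapril).

    Reproducible for a fixed ``seed``; invalid draws are rejected, redrawn
    and counted.
    """
    if n_iterations < 1:
        raise InputError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_iterations, 6))
    n_rejected = 0
    for i in range(n_iterations):
        while True:
            candidate = draw_parameters(params, rng)
            try:
                candidate.validate(life_table, check_ranges=False)
            except (InputError, ModelError) as exc:
                n_rejected += 1
                logger.debug("rejected draw at iteration %d: %s", i, exc)
                continue
            break
        ref = run_strategy(ENALAPRIL, candidate, life_table)
        comp = run_strategy(SV_EARLY, candidate, life_table)
        rows[i] = (
            ref.cost,
            ref.qaly,
            comp.cost,
            comp.qaly,
            comp.cost - ref.cost,
            comp.qaly - ref.qaly,
        )
        if log_every and (i + 1) % log_every == 0:
            logger.info("PSA iteration %d/%d", i + 1, n_iterations)
    samples = pd.DataFrame(
        rows, columns=["cost_ena", "qaly_ena", "cost_sv", "qaly_sv", "d_cost", "d_effect"]
    )
    if n_rejected:
        logger.info("PSA rejected and redrew %d invalid draws", n_rejected)
    return PsaResult(samples=samples, wtp=params.wtp, seed=seed, n_rejected=n_rejected)


# ---------------------------------------------------------------------------
# CEAC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    acceptability: float


def ceac(psa: PsaResult, wtp_grid=CEAC_GRID) -> list[CEACPoint]:
    """Acceptability (fraction of draws with positive incremental NMB) at
    each WTP grid value; the grid must be ascending."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) < 0):
        raise InputError("wtp_grid must be non-empty and ascending")
    d_e = psa.samples["d_effect"].values
    d_c = psa.samples["d_cost"].values
    return [
        CEACPoint(float(w), float(np.mean(w * d_e - d_c > 0.0))) for w in grid
    ]


def ceac_crossing(
    psa: PsaResult, lo: float = 0.0, hi: float = 50_000.0, resolution: float = 0.1
) -> float | None:
    """WTP at which acceptability crosses 0.5, by bisection to ``resolution``
    USD; ``None`` when there is no crossing on ``[lo, hi]``."""
    f_lo = psa.acceptability_at(lo) - 0.5
    f_hi = psa.acceptability_at(hi) - 0.5
    if f_lo >= 0.0 or f_hi < 0.0:
        return None
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if psa.acceptability_at(mid) - 0.5 < 0.0:
            lo = mid
        else:
            hi = mid
    return round(0.5 * (lo + hi), 1)


# ---------------------------------------------------------------------------
# Artifact export
# ---------------------------------------------------------------------------

def _atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    tmp.replace(path)


def write_psa_artifacts(
    outdir: str | Path,
    psa: PsaResult,
    config_path: str | Path | None = None,
    wtp_grid=CEAC_GRID,
) -> dict:
    """Write scatter and CEAC CSVs plus a manifest JSON recording seed, n,
    rejections and the configuration digest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _atomic_write_csv(psa.samples, outdir / "psa_scatter.csv")
    points = ceac(psa, wtp_grid)
    _atomic_write_csv(
        pd.DataFrame([{"wtp": p.wtp, "acceptability": p.acceptability} for p in points]),
        outdir / "ceac.csv",
    )
    manifest = {
        "seed": psa.seed,
        "n_iterations": psa.n,
        "n_rejected": psa.n_rejected,
        "wtp": psa.wtp,
        "acceptability": psa.acceptability,
        "ceac_crossing": ceac_crossing(psa),
        "config_sha256": _digest(config_path) if config_path else None,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    tmp = outdir / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(outdir / "manifest.json")
    return manifest


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
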