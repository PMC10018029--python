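"""Model inputs and derivation arithmetic.

This module houses every input of the decision model — monthly transition
probabilities, monthly drug/standard-care costs, a per-event hospitalization
cost, monthly utilities, the discount rate and the willingness-to-pay
threshold — together with the arithmetic that derives them from raw trial and
registry summary statistics:

* period-to-month conversion of cumulative event proportions via the constant
  rate assumption (rate = -ln(1 - events/at_risk) / period months),
* application of a hazard ratio to the event count *before* conversion,
* inflation of historical CNY costs along a healthcare CPI chain and
  conversion to USD,
* derivation of the annual discount rate as the geometric mean of the CPI
  chain,
* moment matching of beta and gamma distributions for probabilistic
  sensitivity analysis.

Nothing here knows about strategies or the state machine; it is pure input
plumbing shared by the engine, the sensitivity analyses and the CLI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

MONTHS_PER_YEAR = 12

#: Maximum admissible monthly utility: a full quality-adjusted month.
MAX_MONTHLY_UTILITY = 1.0 / MONTHS_PER_YEAR


class InputError(ValueError):
    """Raised when an input violates a precondition (bad counts, bad moments)."""


class ModelError(RuntimeError):
    """Raised when a structurally invalid model would result (e.g. competing
    transition probabilities summing to one or more)."""


# ---------------------------------------------------------------------------
# Rate / probability conversions
# ---------------------------------------------------------------------------

def monthly_prob_from_period(events: float, at_risk: float, period: float) -> float:
    """Convert a cumulative event proportion over ``period`` months to a
    1-month transition probability.

    Assumes a constant event rate over the period:
    ``rate = -ln(1 - events/at_risk) / period`` and
    ``p = 1 - exp(-rate)``, i.e. ``p = 1 - (1 - events/at_risk)**(1/period)``.

    Parameters
    ----------
    events : float
        Number of events observed (0 <= events < at_risk).
    at_risk : float
        Number of subjects at risk (> 0).
    period : float
        Observation period in months (> 0).

    Returns
    -------
    float
        Monthly transition probability in [0, 1).

    Raises
    ------
    InputError
        If ``at_risk`` or ``period`` is non-positive, or ``events`` negative.
    ValueError
        If ``events >= at_risk`` (the log of a non-positive number).
    """
    if at_risk <= 0:
        raise InputError("at_risk must be positive")
    if period <= 0:
        raise InputError("period must be positive (months)")
    if events < 0:
        raise InputError("events must be non-negative")
    frac = events / at_risk
    if frac >= 1.0:
        raise ValueError(f"events/at_risk = {frac} >= 1: rate undefined")
    rate = -math.log1p(-frac) / period
    return -math.expm1(-rate)


def monthly_prob_with_hazard_ratio(
    events: float, at_risk: float, period: float, hr: float
) -> float:
    """Period-to-month conversion after scaling the event count by a hazard
    ratio.

    The hazard ratio is applied to the event *count* before conversion
    (``-ln(1 - hr*events/at_risk) / period``), not to the converted rate.
    At ``hr == 1`` this reduces exactly to :func:`monthly_prob_from_period`.

    Raises
    ------
    InputError
        If ``hr`` is negative.
    ValueError
        If ``hr * events >= at_risk``.
    """
    if hr < 0:
        raise InputError("hazard ratio must be non-negative")
    return monthly_prob_from_period(hr * events, at_risk, period)


# ---------------------------------------------------------------------------
# Cost inflation / currency conversion and discounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpiChain:
    """An ordered chain of annual healthcare CPI multipliers plus the
    CNY-per-USD exchange rate used to express costs in USD.

    The base case covers 2015-2021 with multipliers
    1.027, 1.038, 1.06, 1.043, 1.024, 1.018, 1.004 and exchange rate 6.4515.
    """

    multipliers: tuple[float, ...]
    cny_per_usd: float
    years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers):
            raise InputError("CPI multipliers must be positive")
        if self.cny_per_usd <= 0:
            raise InputError("exchange rate must be positive")
        if self.years and len(self.years) != len(self.multipliers):
            raise InputError("years and multipliers must align")

    @property
    def product(self) -> float:
        return float(np.prod(self.multipliers)) if self.multipliers else 1.0


def inflate_and_convert_cost(cost_cny: float, cpi: CpiChain) -> float:
    """Inflate a historical CNY cost along the CPI chain and convert to USD.

    ``cost_cny * prod(multipliers) / cny_per_usd``; multiplicative, so
    chaining two sub-chains equals one concatenated chain.
    """
    if cost_cny <= 0:
        raise InputError("cost must be positive")
    return cost_cny * cpi.product / cpi.cny_per_usd


def derive_discount_rate(cpi: CpiChain) -> float:
    """Annual discount rate as the geometric mean of the CPI chain minus one.

    Returns the unrounded value (~0.0304 for the 2015-2021 chain); the base
    case works at the rounded 0.03.
    """
    if not cpi.multipliers:
        raise InputError("CPI chain must be non-empty")
    return cpi.product ** (1.0 / len(cpi.multipliers)) - 1.0


# ---------------------------------------------------------------------------
# Distribution moment matching (PSA hyper-parameters)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionSpec:
    """A beta or gamma distribution parameterised by (mean, sd) with derived
    shape hyper-parameters.

    For ``family == "beta"``: ``shape_a`` is alpha, ``shape_b`` is beta.
    For ``family == "gamma"``: ``shape_a`` is the shape k, ``shape_b`` the
    scale theta.
    """

    family: str
    mean: float
    sd: float
    shape_a: float
    shape_b: float

    def draw(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b, size=size)
        return rng.gamma(self.shape_a, self.shape_b, size=size)


def moment_match_beta(mean: float, sd: float) -> DistributionSpec:
    """Beta distribution matching a (mean, sd) pair.

    ``alpha = mean*k``, ``beta = (1-mean)*k`` with
    ``k = mean*(1-mean)/sd**2 - 1``. Requires ``0 < mean < 1`` and
    ``0 < sd**2 < mean*(1-mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise InputError(f"beta mean must lie in (0,1), got {mean}")
    if sd <= 0:
        raise InputError("sd must be positive")
    if sd * sd >= mean * (1.0 - mean):
        raise InputError(f"sd {sd} too large for beta mean {mean}")
    k = mean * (1.0 - mean) / (sd * sd) - 1.0
    return DistributionSpec("beta", mean, sd, mean * k, (1.0 - mean) * k)


def moment_match_gamma(mean: float, sd: float) -> DistributionSpec:
    """Gamma distribution matching a (mean, sd) pair:
    ``shape = (mean/sd)**2``, ``scale = sd**2/mean``."""
    if mean <= 0 or sd <= 0:
        raise InputError("gamma moment matching needs mean > 0 and sd > 0")
    return DistributionSpec("gamma", mean, sd, (mean / sd) ** 2, sd * sd / mean)


# ---------------------------------------------------------------------------
# Background (non-cardiovascular) mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Age-banded monthly non-cardiovascular death probabilities.

    ``band_starts`` are the lower edges of the age bands (years); ages at or
    above the last edge clamp to the last band. Probabilities must be
    non-decreasing with age.
    """

    band_starts: tuple[float, ...]
    monthly_probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.band_starts) != len(self.monthly_probs) or not self.band_starts:
            raise InputError("life table bands and probabilities must align")
        if list(self.band_starts) != sorted(self.band_starts):
            raise InputError("age bands must be ascending")
        if any(not 0.0 < p < 1.0 for p in self.monthly_probs):
            raise InputError("monthly probabilities must lie in (0,1)")
        if list(self.monthly_probs) != sorted(self.monthly_probs):
            raise InputError("mortality must be non-decreasing with age")

    def monthly_prob(self, age: float) -> float:
        if age < self.band_starts[0]:
            raise InputError(
                f"age {age} below first life-table band {self.band_starts[0]}"
            )
        idx = int(np.searchsorted(self.band_starts, age, side="right")) - 1
        return self.monthly_probs[idx]


def noncv_mortality(age: float, table: LifeTable) -> float:
    """Monthly non-cardiovascular death probability at ``age`` (band lookup,
    clamped to the last band for the oldest ages)."""
    return table.monthly_prob(age)


# ---------------------------------------------------------------------------
# The parameter set
# ---------------------------------------------------------------------------

#: Parameters that carry an SD + distribution family and are varied in the PSA.
PSA_PARAMS: tuple[str, ...] = (
    "p_cvd_early_sv",
    "p_cvd_early_ena",
    "p_cvd_late_sv",
    "p_cvd_late_ena",
    "p_hosp_early_sv",
    "p_hosp_early_ena",
    "p_hosp_late_sv",
    "p_hosp_late_ena",
    "cost_sv_month",
    "cost_ena_month",
    "cost_hosp_event",
    "u_sv_month",
    "u_ena_month",
    "u_hosp_event",
)

_PROB_PARAMS = tuple(n for n in PSA_PARAMS if n.startswith("p_"))
_COST_PARAMS = ("cost_sv_month", "cost_ena_month", "cost_hosp_event")
_UTIL_PARAMS = ("u_sv_month", "u_ena_month")


@dataclass(frozen=True)
class ParameterSet:
    """All scalar inputs of the cohort model plus their one-way ranges and
    PSA distribution hyper-parameters.

    Probabilities are monthly. The "early" phase covers the hospitalized month
    and the first two post-discharge months (elevated cardiovascular death and
    readmission risk); the "late"/stable phase starts after three consecutive
    non-hospitalized months. ``cost_ena_month`` is the bundled
    enalapril-plus-standard-care monthly cost; ``cost_sv_month`` is the
    sacubitril-valsartan drug price added on top of standard care when that
    drug is active. ``u_hosp_event`` is the one-off utility decrement per
    hospitalization (negative).
    """

    # transition probabilities (monthly)
    p_cvd_early_sv: float
    p_cvd_early_ena: float
    p_cvd_late_sv: float
    p_cvd_late_ena: float
    p_hosp_early_sv: float
    p_hosp_early_ena: float
    p_hosp_late_sv: float
    p_hosp_late_ena: float
    # costs (USD)
    cost_sv_month: float
    cost_ena_month: float
    cost_hosp_event: float
    # utilities (QALY per month / per event)
    u_sv_month: float
    u_ena_month: float
    u_hosp_event: float
    # framework
    discount_annual: float
    wtp: float
    start_age: float
    horizon_cycles: int
    # uncertainty metadata: name -> (low, high) / sd / family
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    sds: Mapping[str, float] = field(default_factory=dict)
    families: Mapping[str, str] = field(default_factory=dict)

    def value(self, name: str) -> float:
        return getattr(self, name)

    def replace(self, **kwargs) -> "ParameterSet":
        """A copy with some base values replaced (metadata untouched)."""
        return _dc_replace(self, **kwargs)

    # -- validation ---------------------------------------------------------

    def validate(
        self, life_table: LifeTable | None = None, check_ranges: bool = True
    ) -> None:
        """Check every structural invariant; raise ``InputError`` /
        ``ModelError`` naming the offending quantity.

        ``check_ranges=False`` skips the base-within-one-way-range check:
        Monte Carlo draws are legitimate outside those deterministic bounds
        and must not be truncated to them.
        """
        for name in _PROB_PARAMS:
            v = self.value(name)
            if not 0.0 < v < 1.0:
                raise InputError(f"{name}={v} must lie in (0,1)")
        for name in _COST_PARAMS:
            if self.value(name) <= 0:
                raise InputError(f"{name} must be positive")
        for name in _UTIL_PARAMS:
            v = self.value(name)
            if not 0.0 < v <= MAX_MONTHLY_UTILITY:
                raise InputError(
                    f"{name}={v} must lie in (0, 1/12] (QALY per month)"
                )
        if self.u_hosp_event >= 0:
            raise InputError("u_hosp_event must be negative (a decrement)")
        if self.discount_annual < 0:
            raise InputError("discount_annual must be non-negative")
        if self.wtp <= 0:
            raise InputError("wtp must be positive")
        if self.horizon_cycles < 1:
            raise InputError("horizon_cycles must be >= 1")
        # competing-event sums per state must stay below one
        for arm in ("sv", "ena"):
            early = self.value(f"p_cvd_early_{arm}") + self.value(f"p_hosp_early_{arm}")
            if early >= 1.0:
                raise ModelError(
                    f"early-phase competing probabilities sum to {early} >= 1 ({arm})"
                )
            late = self.value(f"p_cvd_late_{arm}") + self.value(f"p_hosp_late_{arm}")
            if life_table is not None:
                late += max(life_table.monthly_probs)
            if late >= 1.0:
                raise ModelError(
                    f"stable-phase competing probabilities sum to {late} >= 1 ({arm})"
                )
        if check_ranges:
            for name, (low, high) in self.ranges.items():
                lo, hi = min(low, high), max(low, high)
                base = self.value(name)
                if not lo <= base <= hi:
                    raise InputError(
                        f"{name}: base {base} outside its range [{lo}, {hi}]"
                    )
        for name, sd in self.sds.items():
            if sd <= 0:
                raise InputError(f"{name}: sd must be positive")

    def distribution(self, name: str) -> DistributionSpec:
        """The PSA distribution of one uncertain parameter.

        Beta for probabilities and monthly utilities; gamma for costs. The
        hospitalization disutility is represented as a beta on its magnitude
        (negated on draw), since a beta cannot carry a negative mean.
        """
        family = self.families[name]
        sd = self.sds[name]
        mean = self.value(name)
        if name == "u_hosp_event":
            mean = abs(mean)
        if family == "beta":
            return moment_match_beta(mean, sd)
        if family == "gamma":
            return moment_match_gamma(mean, sd)
        raise InputError(f"{name}: unknown distribution family {family!r}")

    def to_frame(self) -> pd.DataFrame:
        """Resolved parameter table (one row per input) for audit export."""
        rows = []
        for name in PSA_PARAMS + ("discount_annual", "wtp", "start_age", "horizon_cycles"):
            low, high = self.ranges.get(name, (None, None))
            rows.append(
                {
                    "parameter": name,
                    "base": self.value(name),
                    "low": low,
                    "high": high,
                    "sd": self.sds.get(name),
                    "distribution": self.families.get(name),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Configuration file I/O
# ---------------------------------------------------------------------------

_FRAMEWORK_KEYS = ("wtp", "start_age", "horizon_cycles")


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise InputError(f"missing configuration key {key!r} in {where}")
    return mapping[key]


def load_config(path: str | Path) -> tuple[ParameterSet, LifeTable, CpiChain]:
    """Read a model configuration (YAML) into the three input objects.

    The file holds one ``parameters`` mapping (name -> {base, low, high, sd,
    dist}), the framework scalars, a ``life_table`` mapping of band-start age
    to monthly probability, and a ``cpi`` block (years, multipliers,
    cny_per_usd). Unknown parameter names raise; missing keys raise naming the
    key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"configuration {path} is not a mapping")
    pblock = _require(raw, "parameters", str(path))
    values: dict[str, float] = {}
    ranges: dict[str, tuple[float, float]] = {}
    sds: dict[str, float] = {}
    families: dict[str, str] = {}
    for name in PSA_PARAMS + ("discount_annual",):
        entry = _require(pblock, name, "parameters")
        values[name] = float(_require(entry, "base", name))
        if entry.get("low") is not None and entry.get("high") is not None:
            ranges[name] = (float(entry["low"]), float(entry["high"]))
        if entry.get("sd") is not None:
            sds[name] = float(entry["sd"])
        if entry.get("dist") is not None:
            families[name] = str(entry["dist"])
    unknown = set(pblock) - set(PSA_PARAMS) - {"discount_annual"}
    if unknown:
        raise InputError(f"unknown parameter keys in configuration: {sorted(unknown)}")

    lt_block = _require(raw, "life_table", str(path))
    bands = sorted(float(a) for a in lt_block)
    table = LifeTable(
        band_starts=tuple(bands),
        monthly_probs=tuple(float(lt_block[a]) for a in sorted(lt_block, key=float)),
    )
    cpi_block = _require(raw, "cpi", str(path))
    cpi = CpiChain(
        multipliers=tuple(float(m) for m in _require(cpi_block, "multipliers", "cpi")),
        cny_per_usd=float(_require(cpi_block, "cny_per_usd", "cpi")),
        years=tuple(int(y) for y in cpi_block.get("years", ())),
    )
    params = ParameterSet(
        **values,
        wtp=float(_require(raw, "wtp", str(path))),
        start_age=float(_require(raw, "start_age", str(path))),
        horizon_cycles=int(_require(raw, "horizon_cycles", str(path))),
        ranges=ranges,
        sds=sds,
        families=families,
    )
    params.validate(table)
    return params, table, cpi


def save_config(
    path: str | Path, params: ParameterSet, table: LifeTable, cpi: CpiChain
) -> None:
    """Write a configuration file that :func:`load_config` reads back
    losslessly."""
    pblock = {}
    for name in PSA_PARAMS + ("discount_annual",):
        entry: dict = {"base": params.value(name)}
        if name in params.ranges:
            entry["low"], entry["high"] = params.ranges[name]
        if name in params.sds:
            entry["sd"] = params.sds[name]
        if name in params.families:
            entry["dist"] = params.families[name]
        pblock[name] = entry
    doc = {
        "parameters": pblock,
        "wtp": params.wtp,
        "start_age": params.start_age,
        "horizon_cycles": params.horizon_cycles,
        "life_table": {
            float(a): float(p)
            for a, p in zip(table.band_starts, table.monthly_probs)
        },
        "cpi": {
            "years": list(cpi.years),
            "multipliers": list(cpi.multipliers),
            "cny_per_usd": cpi.cny_per_usd,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
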