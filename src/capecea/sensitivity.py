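"""One-way (tornado) and probabilistic sensitivity analyses.

One-way analysis reruns the full base-case pipeline with a single entry at
its lower and upper bound. The PSA samples every entry from its configured
distribution — gamma for costs, beta for incidences/(dis)utilities, both
moment-matched to mean = base and SD = (high - low)/3.92 (the range read as
a 95% interval), and a uniform ±5% multiplier applied per (arm, endpoint)
to the monthly exit probabilities of the survival curves. The discount rate
is fixed in the PSA and varied only one-way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError
from .parameters import ARMS, ENDPOINTS, LifeTable, ParamEntry, ParameterSet
from .pipeline import base_case, icer_for

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSAResult:
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int
    base_icer: float
    wtp: float

    @property
    def n_iter(self) -> int:
        return len(self.delta_cost)

    def icers(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.delta_cost / self.delta_qaly

    def prob_cost_effective(self, wtp: float | None = None) -> float:
        """Fraction of draws with positive net monetary benefit at the WTP."""
        wtp = self.wtp if wtp is None else wtp
        return float(np.mean(wtp * self.delta_qaly - self.delta_cost > 0.0))

    def icer_ci(self, level: float = 0.95) -> tuple[float, float, int]:
        """Percentile CI of the ICER over positive-quadrant draws.

        Returns (low, high, n_quadrant_crossers); draws outside the
        cost-up/QALY-up quadrant are counted and excluded from the ratio.
        """
        inside = (self.delta_cost > 0.0) & (self.delta_qaly > 0.0)
        crossers = int(np.sum(~inside))
        if not np.any(inside):
            raise DomainError("no draws in the positive-delta quadrant")
        ratios = self.delta_cost[inside] / self.delta_qaly[inside]
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(ratios, [alpha, 1.0 - alpha])
        return float(lo), float(hi), crossers

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iter),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


# ---------------------------------------------------------------------------
# one-way


def one_way(params: ParameterSet, life_table: LifeTable, name: str) -> TornadoEntry:
    """ICER with one entry pinned at its lower / upper bound, all else base."""
    if name not in params.entries:
        raise DomainError(f"unknown parameter entry {name!r}")
    entry = params.entries[name]
    icers = {}
    for bound, value in (("low", entry.low), ("high", entry.high)):
        scenario = _pin(params, name, value)
        icers[bound] = icer_for(scenario, life_table).icer
    return TornadoEntry(name=name, icer_at_low=icers["low"], icer_at_high=icers["high"])


def _pin(params: ParameterSet, name: str, value: float) -> ParameterSet:
    if name == "transition_multiplier":
        return params.with_transition_multipliers(
            {(a, e): value for a in ARMS for e in ENDPOINTS}
        )
    return params.with_value(name, value)


def tornado(
    params: ParameterSet, life_table: LifeTable, entries: Sequence[str] | None = None
) -> list[TornadoEntry]:
    """One-way entries ordered by descending ICER spread (stable for ties)."""
    names = list(entries) if entries is not None else params.varying_entries()
    results = [one_way(params, life_table, n) for n in names]
    return sorted(results, key=lambda e: -e.spread)


# ---------------------------------------------------------------------------
# PSA sampling


def _range_sd(entry: ParamEntry) -> float:
    return (entry.high - entry.low) / 3.92


def _sample_entry(entry: ParamEntry, rng: np.random.Generator) -> float:
    sd = _range_sd(entry)
    m = entry.base
    if entry.psa_distribution == "fixed" or sd == 0.0:
        return m
    if entry.psa_distribution == "gamma":
        if m <= 0.0:
            return m
        shape = (m / sd) ** 2
        return float(rng.gamma(shape, scale=sd * sd / m))
    if entry.psa_distribution == "beta":
        max_var = m * (1.0 - m)
        var = sd * sd
        if var >= max_var:
            # moment match infeasible on (0,1); fall back to the largest
            # feasible variance (documented convention)
            logger.warning(
                "beta entry %s: variance %.4g capped at %.4g", entry.name, var, 0.99 * max_var
            )
            var = 0.99 * max_var
        nu = m * (1.0 - m) / var - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    raise DomainError(
        f"entry {entry.name}: distribution {entry.psa_distribution!r} is not "
        "drawn per-entry"
    )


def sample_params(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: every non-fixed entry resampled, multipliers perturbed."""
    values = {}
    for name, entry in params.entries.items():
        if entry.psa_distribution in ("fixed", "uniform"):
            continue
        values[name] = _sample_entry(entry, rng)
    mult_entry = params.entries["transition_multiplier"]
    multipliers = {
        (arm, ep): float(rng.uniform(mult_entry.low, mult_entry.high))
        for arm in ARMS
        for ep in ENDPOINTS
    }
    drawn = params.with_values(values).with_transition_multipliers(multipliers)
    return drawn


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    n_iter: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Monte-Carlo PSA: ``n_iter`` independent full pipeline evaluations."""
    if n_iter < 1:
        raise DomainError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    base = base_case(params, life_table).ce
    dc = np.empty(n_iter)
    dq = np.empty(n_iter)
    for i in range(n_iter):
        draw = sample_params(params, rng)
        ce = icer_for(draw, life_table)
        dc[i] = ce.delta_cost
        dq[i] = ce.delta_qaly
    return PSAResult(
        delta_cost=dc,
        delta_qaly=dq,
        seed=seed,
        base_icer=base.icer if base.icer is not None else np.nan,
        wtp=params.wtp_threshold,
    )


def ceac(psa: PSAResult, wtp_grid: Iterable[float]) -> np.ndarray:
    """P(cost-effective) at each willingness-to-pay value."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if psa.n_iter == 0:
        raise DomainError("empty PSA draws")
    nmb = grid[:, None] * psa.delta_qaly[None, :] - psa.delta_cost[None, :]
    return (nmb > 0.0).mean(axis=1)


def ceac_crossing(psa: PSAResult, level: float = 0.5) -> float:
    """Smallest WTP on a fine grid at which the CEAC reaches ``level``."""
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(psa.delta_qaly > 0, psa.delta_cost / psa.delta_qaly, np.inf)
    return float(np.quantile(icers, level))
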