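"""Copy-number sensitivity sweeps, rankings, and perturbation reports.

For each gene unit the copy factor X/X0 is swept over an exponential grid
(default 0.001 to 1000), one full fermentation simulation per point, each
starting from the same unperturbed network.  The maximum sensitivity is
``max (Y - Y0) / Y0`` over the curve and the scale factor is the X/X0 at
which it is attained (ties broken toward the factor nearest 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ConfigurationError, ReactionNetwork
from .simulation_engine import (
    GrowthInfeasibleError,
    GrowthProfile,
    SimulationConfig,
    SimulationError,
    apply_copy_factor,
    simulate,
    yield_metric,
)

__all__ = [
    "PerturbationGrid",
    "SensitivityResult",
    "SweepError",
    "default_grid",
    "sweep_gene",
    "rank_all",
    "dose_response",
    "snapshot_relative_changes",
]

log = logging.getLogger(__name__)


class SweepError(RuntimeError):
    """More than half of a sweep's member simulations failed."""


@dataclass
class PerturbationGrid:
    """Ordered positive multipliers; the paper-default grid is log-spaced
    over [0.001, 1000] and always contains 1."""

    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.size == 0:
            raise ConfigurationError("empty perturbation grid")
        if np.any(self.factors <= 0):
            raise ConfigurationError("grid factors must be > 0")
        if np.any(np.diff(self.factors) <= 0):
            raise ConfigurationError("grid factors must be strictly increasing")
        if not np.any(np.isclose(self.factors, 1.0)):
            raise ConfigurationError("grid must contain the baseline factor 1")


def default_grid(
    lo: float = 0.001, hi: float = 1000.0, points: int = 61
) -> PerturbationGrid:
    """Log-spaced grid that contains 1 exactly when lo*hi == 1."""
    factors = np.power(10.0, np.linspace(math.log10(lo), math.log10(hi), points))
    # snap the point nearest 1 onto exactly 1 so the baseline is in-grid
    i = int(np.argmin(np.abs(np.log10(factors))))
    factors[i] = 1.0
    return PerturbationGrid(factors)


@dataclass
class SensitivityResult:
    gene_unit: str
    curve: list[tuple[float, float]]  # (factor X/X0, yield Y); failures omitted
    Y0: float
    max_sensitivity: float
    scale_factor: float
    failed_factors: list[float] = field(default_factory=list)
    infeasible_factors: list[float] = field(default_factory=list)
    description: str = ""

    def yield_at(self, factor: float) -> float:
        for f, y in self.curve:
            if np.isclose(f, factor):
                return y
        raise KeyError(f"factor {factor} not in curve")


#: sensitivities below this are integrator jitter, not signal
FLAT_TOLERANCE = 1e-9


def _argmax_tiebreak(factors: np.ndarray, sens: np.ndarray) -> int:
    """Index of the maximum; among (near-)ties, the factor nearest 1."""
    best = sens.max()
    ties = np.where(np.isclose(sens, best, rtol=0, atol=FLAT_TOLERANCE))[0]
    return int(ties[np.argmin(np.abs(np.log10(factors[ties])))])


def sweep_gene(
    network: ReactionNetwork,
    profile: GrowthProfile,
    config: SimulationConfig,
    gene_unit: str,
    grid: PerturbationGrid | None = None,
    baseline: float | None = None,
) -> SensitivityResult:
    """Sweep one unit's copy factor over the grid and summarise the curve.

    Each grid point is simulated from the unperturbed network with only
    that unit's copy factor scaled.  ``baseline`` (Y0) may be supplied to
    avoid recomputing it across sweeps.
    """
    grid = grid or default_grid()
    unit = network.get_gene_unit(gene_unit)  # raises for unknown ids
    if baseline is None:
        baseline = yield_metric(simulate(network, profile, config))
    curve: list[tuple[float, float]] = []
    failed: list[float] = []
    infeasible: list[float] = []
    for factor in grid.factors:
        if np.isclose(factor, 1.0):
            curve.append((1.0, baseline))
            continue
        try:
            net = apply_copy_factor(network, gene_unit, float(factor))
            y = yield_metric(simulate(net, profile, config))
            curve.append((float(factor), y))
        except GrowthInfeasibleError as exc:
            # a dosage that cannot feed the prescribed growth is lethal in
            # context: productive yield is zero, not unknown
            log.info("sweep %s factor %g infeasible: %s", gene_unit, factor, exc)
            curve.append((float(factor), 0.0))
            infeasible.append(float(factor))
        except SimulationError as exc:
            log.warning("sweep %s factor %g failed: %s", gene_unit, factor, exc)
            failed.append(float(factor))
    if len(failed) > grid.factors.size / 2:
        raise SweepError(
            f"sweep of {gene_unit!r}: {len(failed)}/{grid.factors.size} "
            "simulations failed"
        )
    factors = np.array([f for f, _ in curve])
    sens = (np.array([y for _, y in curve]) - baseline) / baseline
    i = _argmax_tiebreak(factors, sens)
    if abs(sens[i]) < FLAT_TOLERANCE:  # flat curve: declared tie-break
        sens[i] = 0.0
        i = int(np.argmin(np.abs(np.log10(factors))))
    log.debug(
        "sweep %s: max sensitivity %.5g at factor %g", gene_unit, sens[i], factors[i]
    )
    return SensitivityResult(
        gene_unit=gene_unit,
        curve=curve,
        Y0=baseline,
        max_sensitivity=float(sens[i]),
        scale_factor=float(factors[i]),
        failed_factors=failed,
        infeasible_factors=infeasible,
        description=unit.description,
    )


def rank_all(
    network: ReactionNetwork,
    profile: GrowthProfile,
    config: SimulationConfig,
    grid: PerturbationGrid | None = None,
    units: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, SensitivityResult]]:
    """Sweep every perturbable unit and rank by maximum sensitivity.

    Returns the ranking table (rank, unit, product, max_sensitivity,
    scale_factor; descending, ties broken by unit id) and the per-unit
    results.  Units whose sweep fails are excluded and logged.
    """
    grid = grid or default_grid()
    if units is None:
        units = [u.id for u in network.gene_units if not u.removed]
    if not units:
        raise ConfigurationError("no perturbable gene units")
    baseline = yield_metric(simulate(network, profile, config))
    results: dict[str, SensitivityResult] = {}
    for uid in units:
        try:
            results[uid] = sweep_gene(network, profile, config, uid, grid, baseline)
        except (SweepError, SimulationError) as exc:
            log.warning("excluding unit %s from ranking: %s", uid, exc)
    rows = sorted(
        results.values(), key=lambda r: (-r.max_sensitivity, r.gene_unit)
    )
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "unit": [r.gene_unit for r in rows],
            "product": [r.description for r in rows],
            "max_sensitivity": [r.max_sensitivity for r in rows],
            "scale_factor": [r.scale_factor for r in rows],
        }
    )
    return table, results


def dose_response(
    network: ReactionNetwork,
    profile: GrowthProfile,
    config: SimulationConfig,
    gene_unit: str,
    grid: PerturbationGrid | None = None,
    observables: list[str] | None = None,
) -> pd.DataFrame:
    """End-point concentration ratios vs. baseline across the sweep grid.

    One row per grid factor; one column per observable holding
    ``observable(t_end) / baseline(t_end)``.  At factor 1 all ratios are 1.
    """
    grid = grid or default_grid()
    if not observables:
        raise ConfigurationError("no observables given")
    base_tc = simulate(network, profile, config)
    base = {}
    for sid in observables:
        val = base_tc.final(sid)
        if val == 0:
            raise SimulationError(f"baseline end-point of {sid!r} is zero")
        base[sid] = val
    rows = []
    for factor in grid.factors:
        if np.isclose(factor, 1.0):
            rows.append({"factor": 1.0, **{s: 1.0 for s in observables}})
            continue
        net = apply_copy_factor(network, gene_unit, float(factor))
        tc = simulate(net, profile, config)
        rows.append(
            {"factor": float(factor), **{s: tc.final(s) / base[s] for s in observables}}
        )
    return pd.DataFrame(rows)


def snapshot_relative_changes(
    network: ReactionNetwork,
    profile: GrowthProfile,
    config: SimulationConfig,
    gene_unit: str,
    factor: float,
) -> dict[str, float]:
    """End-point concentration ratio vs. baseline for every dynamic pool.

    Covers metabolites, mRNAs and proteins (boundary species excluded);
    pools at zero in both runs report a ratio of 1.
    """
    if factor <= 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    base_tc = simulate(network, profile, config)
    net = apply_copy_factor(network, gene_unit, float(factor))
    tc = simulate(net, profile, config)
    out: dict[str, float] = {}
    for sp in network.species:
        if sp.role == "boundary":
            continue
        b = base_tc.final(sp.id)
        p = tc.final(sp.id)
        if b == 0 and p == 0:
            out[sp.id] = 1.0
        elif b == 0:
            out[sp.id] = math.inf
        else:
            out[sp.id] = p / b
    return out
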