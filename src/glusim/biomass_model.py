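"""Summation biomass model.

Growth drains key precursor metabolites from the network in proportion to
the biomass formed, according to a composition table (mmol per g dry cell
weight).  Sign semantics follow the summation convention: a positive
coefficient means the precursor is consumed for biomass, a negative one
means it is produced alongside biomass.  An accepted table must carry
positive coefficients for OAA and FUM and must list branch-point key
substances (S7P).

Also provided: the minimum-norm (pseudoinverse) combination of parallel
branch-point routes into a single mass-balance expression, and the three
fixed side reactions (revised arginine route, revised purine route,
glycogen synthesis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    ConfigurationError,
    RateLaw,
    Reaction,
    ReactionNetwork,
    ResolutionError,
)

__all__ = [
    "PrecursorCoefficient",
    "BranchCombination",
    "SIDE_REACTIONS",
    "combine_branch_routes",
    "validate_precursor_table",
    "biomass_drain",
    "apply_side_reactions",
]

#: Species drained per unit of biomass, positive = consumed.
@dataclass
class PrecursorCoefficient:
    species: str
    coefficient: float  # mmol per g dry biomass


@dataclass
class BranchCombination:
    """Combined mass-balance expression for one branch-point metabolite.

    ``coefficients`` maps species -> coefficient in the expression
    ``1 target = sum_j c_j * species_j`` (positive = consumed to make the
    target, negative = co-produced).
    """

    target: str
    routes: list[dict[str, float]]
    coefficients: dict[str, float] = field(default_factory=dict)


# Fixed stoichiometries of the revised side reactions.  Per unit flux the
# arginine route releases 4 CO2 and regenerates 6 NADH, 2 FADH and 2 ATP
# from the oxidised/low-energy pools; the purine route is the identical
# pattern on SAICAR -> AICAR.  Glycogen synthesis consumes 8 G6P + 8 ATP.
SIDE_REACTIONS: dict[str, dict[str, float]] = {
    "eqA": {
        "ARGSUC": -1.0,
        "ARG": 1.0,
        "CO2": 4.0,
        "NAD": -6.0,
        "NADH": 6.0,
        "FAD": -2.0,
        "FADH": 2.0,
        "ADP": -2.0,
        "Pi": -2.0,
        "ATP": 2.0,
    },
    "eqB": {
        "SAICAR": -1.0,
        "AICAR": 1.0,
        "CO2": 4.0,
        "NAD": -6.0,
        "NADH": 6.0,
        "FAD": -2.0,
        "FADH": 2.0,
        "ADP": -2.0,
        "Pi": -2.0,
        "ATP": 2.0,
    },
    "glycogen": {
        "G6P": -8.0,
        "ATP": -8.0,
        "GLYCOGEN": 1.0,
        "ADP": 8.0,
        "Pi": 8.0,
    },
}


def combine_branch_routes(
    routes: list[dict[str, float]], target: str
) -> BranchCombination:
    """Combine parallel routes producing one target into a single expression.

    Each route is a signed stoichiometry map that must produce exactly one
    unit of ``target``.  The combined per-unit-target composition is the
    minimum-norm solution for the route fluxes: with k independent routes
    each constrained only by total target production of 1, the pseudoinverse
    assigns flux 1/k to each route, so the combined coefficients are the
    unweighted average of the per-route expressions.
    """
    if not routes:
        raise ConfigurationError("no routes given")
    for i, route in enumerate(routes):
        if route.get(target) is None:
            raise ConfigurationError(f"route {i} does not involve target {target!r}")
        if abs(route[target] - 1.0) > 1e-12:
            raise ConfigurationError(
                f"route {i} produces {route[target]} units of {target!r}, expected 1"
            )
    k = len(routes)
    # minimum-norm fluxes: pinv of the 1 x k production-constraint row
    A = np.ones((1, k))
    v = np.linalg.pinv(A) @ np.array([1.0])  # each entry 1/k
    combined: dict[str, float] = {}
    for route, vj in zip(routes, v):
        for sid, coeff in route.items():
            if sid == target:
                continue
            # expression coefficient: consumed species (coeff<0) enter with +
            combined[sid] = combined.get(sid, 0.0) + float(vj) * (-coeff)
    combined = {s: c for s, c in combined.items() if abs(c) > 1e-12}
    return BranchCombination(target=target, routes=list(routes), coefficients=combined)


#: Branch-point key substances that must appear in any accepted table.
BRANCH_POINT_KEY_SUBSTANCES = ("S7P",)


def validate_precursor_table(table: list[PrecursorCoefficient]) -> list[str]:
    """Return the list of rule violations (empty iff the table is accepted).

    Rules: OAA and FUM coefficients must be present and positive (consumed
    for biomass, never produced alongside it), and branch-point key
    substances (S7P) must be listed.
    """
    violations: list[str] = []
    by_species = {entry.species: entry.coefficient for entry in table}
    for sid in ("OAA", "FUM"):
        if sid not in by_species:
            violations.append(f"{sid} missing from precursor table")
        elif by_species[sid] <= 0:
            violations.append(
                f"{sid} coefficient must be positive, got {by_species[sid]}"
            )
    for sid in BRANCH_POINT_KEY_SUBSTANCES:
        if sid not in by_species:
            violations.append(f"branch-point key substance absent: {sid}")
    return violations


def biomass_drain(
    table: list[PrecursorCoefficient],
    mu: float,
    X: float,
    volume_factor: float = 1.0,
) -> dict[str, float]:
    """Per-species drain rates (mM/min) at growth rate ``mu`` and density ``X``.

    ``drain = coefficient [mmol/g] * mu [1/min] * X [g/L] * volume_factor``;
    with the 1 L culture basis, mmol/g * g/L = mM.  Negative coefficients
    yield negative drains (production alongside biomass).
    """
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    if X < 0:
        raise ValueError(f"X must be >= 0, got {X}")
    rate = mu * X * volume_factor
    return {entry.species: entry.coefficient * rate for entry in table}


def apply_side_reactions(
    network: ReactionNetwork,
    which: tuple[str, ...] = ("eqA", "eqB", "glycogen"),
    rate_constants: dict[str, float] | None = None,
) -> ReactionNetwork:
    """Return a new network with the fixed side reactions installed.

    Each side reaction is added as an uncatalysed mass-action step (first
    order in its consumed organic substrate) with a small default rate
    constant, overridable per reaction through ``rate_constants``.
    Missing species raise :class:`ResolutionError` naming the offender.
    """
    rate_constants = rate_constants or {}
    ids = {sp.id for sp in network.species}
    new_reactions = list(network.reactions)
    existing = {r.id for r in new_reactions}
    for name in which:
        if name not in SIDE_REACTIONS:
            raise ConfigurationError(f"unknown side reaction {name!r}")
        stoich = SIDE_REACTIONS[name]
        missing = sorted(set(stoich) - ids)
        if missing:
            raise ResolutionError(
                f"side reaction {name!r}: missing species {', '.join(missing)}"
            )
        rid = f"biomass_{name}"
        if rid in existing:
            raise ConfigurationError(f"side reaction {rid!r} already installed")
        k = rate_constants.get(name, 1e-3)
        # first-order only in the organic substrate; clamped cofactors are
        # stoichiometric participants but not kinetic ones
        driver = {"eqA": "ARGSUC", "eqB": "SAICAR", "glycogen": "G6P"}[name]
        law = RateLaw(form="irreversible_mm", kcat=k, Km={driver: 1.0})
        new_reactions.append(
            Reaction(id=rid, stoichiometry=dict(stoich), rate_law=law, catalyst=None)
        )
    return ReactionNetwork(
        species=network.species,
        reactions=new_reactions,
        cycles=network.cycles,
        gene_units=network.gene_units,
        machinery=network.machinery,
        biomass=network.biomass,
    )
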