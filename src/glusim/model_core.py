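"""Core data model for the kinetic reaction network.

Species, Michaelis-Menten rate laws, reactions, the isocitrate-dehydrogenase
phosphorylation cycle, and the assembled :class:`ReactionNetwork` with its
stoichiometric matrix.

Conventions
-----------
* Units: mM, minutes, litres, g dry cell weight.
* Multi-substrate Michaelis-Menten rates are products of independent
  saturation terms (no ternary-complex mechanism).
* Inhibition is a hyperbolic multiplier ``1 / (1 + I/Ki)`` applied to the
  whole rate (noncompetitive-style).
* Reversible reactions use a Keq-scaled net-rate form (see :func:`mm_rate`).
* Saturating activator "modifiers" (e.g. the IIA component acting on the
  PTS permease) multiply the rate by ``M / (K + M)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Species",
    "RateLaw",
    "Reaction",
    "ModificationCycle",
    "ReactionNetwork",
    "ModelDefinition",
    "ConfigurationError",
    "ResolutionError",
    "inhibition_factor",
    "mm_rate",
    "modification_fluxes",
    "build_network",
]

ROLES = ("metabolite", "protein", "mRNA", "boundary")
COMPARTMENTS = ("intracellular", "extracellular")
RATE_FORMS = ("irreversible_mm", "reversible_mm", "mass_action")


class ConfigurationError(ValueError):
    """A model definition or rate-law reference does not resolve."""


class ResolutionError(ConfigurationError):
    """A cross-reference names an id that does not exist in the network."""


@dataclass
class Species:
    """A chemical or macromolecular pool.

    ``boundary`` species are clamped at their initial concentration: they
    are never integrated, never diluted and never drained by biomass.
    """

    id: str
    role: str = "metabolite"
    concentration: float = 0.0
    compartment: str = "intracellular"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.compartment not in COMPARTMENTS:
            raise ConfigurationError(
                f"species {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.concentration < 0:
            raise ConfigurationError(
                f"species {self.id!r}: negative concentration {self.concentration}"
            )


@dataclass
class RateLaw:
    """Kinetic form of one reaction.

    ``Km`` maps participating species ids to their half-saturation constants;
    the split into substrates/products is taken from the owning reaction's
    stoichiometry when the law is bound (see :meth:`Reaction.bind`).
    ``inhibitors`` is a list of ``(species_id, Ki, mode)`` tuples and
    ``modifiers`` a list of ``(species_id, K_half)`` saturating activators.
    """

    form: str = "irreversible_mm"
    kcat: float = 1.0
    Km: dict[str, float] = field(default_factory=dict)
    Keq: float | None = None
    inhibitors: list[tuple[str, float, str]] = field(default_factory=list)
    modifiers: list[tuple[str, float]] = field(default_factory=list)
    substrates: list[str] = field(default_factory=list)
    products: list[str] = field(default_factory=list)
    orders: dict[str, float] = field(default_factory=dict)  # mass_action only

    def __post_init__(self) -> None:
        if self.form not in RATE_FORMS:
            raise ConfigurationError(f"unknown rate-law form {self.form!r}")
        if self.kcat <= 0:
            raise ConfigurationError(f"kcat must be > 0, got {self.kcat}")
        for sid, km in self.Km.items():
            if km <= 0:
                raise ConfigurationError(f"Km[{sid!r}] must be > 0, got {km}")
        for sid, ki, _mode in self.inhibitors:
            if ki <= 0:
                raise ConfigurationError(f"Ki for {sid!r} must be > 0, got {ki}")
        for sid, k in self.modifiers:
            if k <= 0:
                raise ConfigurationError(f"modifier K for {sid!r} must be > 0, got {k}")
        if self.form == "reversible_mm" and self.Keq is None:
            raise ConfigurationError("reversible_mm requires Keq")
        if self.Keq is not None and self.Keq <= 0:
            raise ConfigurationError(f"Keq must be > 0, got {self.Keq}")


@dataclass
class Reaction:
    """One reaction: signed stoichiometry plus a bound rate law.

    Negative stoichiometric coefficients are consumed, positive produced.
    ``catalyst`` names a protein species, or ``None`` for uncatalysed steps.
    """

    id: str
    stoichiometry: dict[str, float]
    rate_law: RateLaw
    catalyst: str | None = None

    def __post_init__(self) -> None:
        neg = [s for s, c in self.stoichiometry.items() if c < 0]
        pos = [s for s, c in self.stoichiometry.items() if c > 0]
        if not neg and not pos:
            raise ConfigurationError(f"reaction {self.id!r}: empty stoichiometry")
        # exchange reactions (pure source/sink) are allowed with one side only
        self.bind()

    def bind(self) -> None:
        """Derive the rate law's substrate/product lists from stoichiometry.

        Only species with a Km entry participate kinetically (this lets
        clamped cofactors appear in the stoichiometry without a rate term).
        For mass_action, every consumed species participates first-order.
        """
        law = self.rate_law
        if law.form == "mass_action":
            law.substrates = [s for s, c in self.stoichiometry.items() if c < 0]
            law.products = [s for s, c in self.stoichiometry.items() if c > 0]
            law.orders = {s: -self.stoichiometry[s] for s in law.substrates}
            return
        law.substrates = [
            s for s, c in self.stoichiometry.items() if c < 0 and s in law.Km
        ]
        law.products = [
            s for s, c in self.stoichiometry.items() if c > 0 and s in law.Km
        ]
        if law.form in ("irreversible_mm", "reversible_mm") and not law.substrates:
            raise ConfigurationError(
                f"reaction {self.id!r}: no substrate carries a Km entry"
            )


@dataclass
class ModificationCycle:
    """Covalent-modification (phosphorylation) cycle on a target protein.

    A single bifunctional converter enzyme carries both the kinase and the
    phosphatase activity; only the unmodified target is catalytically
    active.  The kinase leg is inhibited hyperbolically by
    ``kinase_inhibitor`` (3-phosphoglycerate in the reference model).
    """

    target: str
    modified_form: str
    converter: str
    k_kin: float
    k_phos: float
    kinase_inhibitor: str | None = None
    Ki_inh: float | None = None
    Km_kin: float = 1.0
    Km_phos: float = 1.0
    id: str = "cycle"

    def __post_init__(self) -> None:
        for name in ("k_kin", "k_phos", "Km_kin", "Km_phos"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"cycle {self.id!r}: {name} must be > 0")
        if self.kinase_inhibitor is not None and (
            self.Ki_inh is None or self.Ki_inh <= 0
        ):
            raise ConfigurationError(
                f"cycle {self.id!r}: kinase inhibitor requires Ki_inh > 0"
            )


def inhibition_factor(inhibitor_conc: float, Ki: float) -> float:
    """Hyperbolic inhibition multiplier ``1 / (1 + I/Ki)`` in (0, 1]."""
    if Ki <= 0:
        raise ConfigurationError(f"Ki must be > 0, got {Ki}")
    if inhibitor_conc < 0:
        raise ValueError(f"inhibitor concentration must be >= 0, got {inhibitor_conc}")
    return 1.0 / (1.0 + inhibitor_conc / Ki)


def _regulation_factor(law: RateLaw, concs: dict[str, float]) -> float:
    f = 1.0
    for sid, ki, _mode in law.inhibitors:
        if sid not in concs:
            raise ConfigurationError(f"missing inhibitor concentration for {sid!r}")
        f *= inhibition_factor(max(concs[sid], 0.0), ki)
    for sid, k in law.modifiers:
        if sid not in concs:
            raise ConfigurationError(f"missing modifier concentration for {sid!r}")
        m = max(concs[sid], 0.0)
        f *= m / (k + m)
    return f


def mm_rate(
    rate_law: RateLaw, enzyme_conc: float, substrate_concs: dict[str, float]
) -> float:
    """Evaluate one rate law at the given enzyme and species concentrations.

    irreversible_mm:
        ``kcat * E * prod_i S_i/(Km_i + S_i)``  times regulation factors.
    reversible_mm (Keq-scaled net rate):
        ``kcat * E * (prod_i S_i - prod_j P_j / Keq) / (prod_i Km_i * D)``
        with ``D = prod_i (1 + S_i/Km_i) + prod_j (1 + P_j/Km_j) - 1``;
        the net rate vanishes exactly at the concentration equilibrium
        ``prod P / prod S = Keq``.
    mass_action:
        ``kcat * E * prod_i S_i^|n_i|`` (``E`` = 1 when uncatalysed).

    Negative concentrations raise; missing entries raise
    :class:`ConfigurationError`.
    """
    if enzyme_conc < 0:
        raise ValueError(f"enzyme concentration must be >= 0, got {enzyme_conc}")

    def conc(sid: str) -> float:
        if sid not in substrate_concs:
            raise ConfigurationError(f"missing concentration for species {sid!r}")
        c = substrate_concs[sid]
        if c < 0:
            raise ValueError(f"concentration of {sid!r} must be >= 0, got {c}")
        return c

    law = rate_law
    reg = _regulation_factor(law, substrate_concs)
    if law.form == "mass_action":
        v = law.kcat * enzyme_conc
        for sid in law.substrates:
            v *= conc(sid) ** law.orders.get(sid, 1.0)
        return v * reg
    if law.form == "irreversible_mm":
        v = law.kcat * enzyme_conc
        for sid in law.substrates:
            s = conc(sid)
            v *= s / (law.Km[sid] + s)
        return v * reg
    # reversible_mm
    fwd = 1.0
    den_s = 1.0
    km_s = 1.0
    for sid in law.substrates:
        s = conc(sid)
        km_s *= law.Km[sid]
        fwd *= s
        den_s *= 1.0 + s / law.Km[sid]
    rev = 1.0 / law.Keq
    den_p = 1.0
    for sid in law.products:
        p = conc(sid)
        rev *= p
        den_p *= 1.0 + p / law.Km[sid]
    return (
        law.kcat * enzyme_conc * (fwd - rev) / (km_s * (den_s + den_p - 1.0)) * reg
    )


def modification_fluxes(
    cycle: ModificationCycle, concs: dict[str, float]
) -> tuple[float, float]:
    """Kinase and phosphatase fluxes (mM/min) of a modification cycle.

    ``kinase_flux``  converts target -> modified form;
    ``phosphatase_flux`` converts modified form -> target.
    The net contribution to ``[target] + [modified_form]`` is exactly zero.
    """
    for sid in (cycle.target, cycle.modified_form, cycle.converter):
        if sid not in concs:
            raise ConfigurationError(f"cycle {cycle.id!r}: missing species {sid!r}")
    conv = max(concs[cycle.converter], 0.0)
    tgt = max(concs[cycle.target], 0.0)
    mod = max(concs[cycle.modified_form], 0.0)
    inh = 1.0
    if cycle.kinase_inhibitor is not None:
        if cycle.kinase_inhibitor not in concs:
            raise ConfigurationError(
                f"cycle {cycle.id!r}: missing inhibitor {cycle.kinase_inhibitor!r}"
            )
        inh = inhibition_factor(max(concs[cycle.kinase_inhibitor], 0.0), cycle.Ki_inh)
    kinase = cycle.k_kin * conv * inh * tgt / (cycle.Km_kin + tgt)
    phosphatase = cycle.k_phos * conv * mod / (cycle.Km_phos + mod)
    return kinase, phosphatase


@dataclass
class ModelDefinition:
    """Parsed model definition prior to network assembly."""

    species: list = field(default_factory=list)
    reactions: list = field(default_factory=list)
    cycles: list = field(default_factory=list)
    gene_units: list = field(default_factory=list)
    machinery: object | None = None
    biomass: list = field(default_factory=list)


class ReactionNetwork:
    """Assembled network: species, reactions, cycles, gene units, S matrix.

    Column ``j`` of :attr:`S` is reaction ``j``'s stoichiometry over the
    species index; assembly is deterministic (identical definitions yield
    identical matrices).
    """

    def __init__(
        self,
        species: list[Species],
        reactions: list[Reaction],
        cycles: list[ModificationCycle] | None = None,
        gene_units: list | None = None,
        machinery=None,
        biomass: list | None = None,
    ):
        self.species = list(species)
        self.reactions = list(reactions)
        self.cycles = list(cycles or [])
        self.gene_units = list(gene_units or [])
        self.machinery = machinery
        self.biomass = list(biomass or [])
        self._validate()
        self.species_index = {sp.id: i for i, sp in enumerate(self.species)}
        self.S = self._build_matrix()

    # -- assembly -----------------------------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for sp in self.species:
            if sp.id in seen:
                raise ConfigurationError(f"duplicate species id {sp.id!r}")
            seen.add(sp.id)
        rids: set[str] = set()
        for rxn in self.reactions:
            if rxn.id in rids:
                raise ConfigurationError(f"duplicate reaction id {rxn.id!r}")
            rids.add(rxn.id)
            for sid in rxn.stoichiometry:
                if sid not in seen:
                    raise ResolutionError(
                        f"reaction {rxn.id!r} references undeclared species {sid!r}"
                    )
            if rxn.catalyst is not None and rxn.catalyst not in seen:
                raise ResolutionError(
                    f"reaction {rxn.id!r} references undeclared catalyst "
                    f"{rxn.catalyst!r}"
                )
            law = rxn.rate_law
            for sid in list(law.Km) + [i[0] for i in law.inhibitors] + [
                m[0] for m in law.modifiers
            ]:
                if sid not in seen:
                    raise ResolutionError(
                        f"reaction {rxn.id!r} rate law references undeclared "
                        f"species {sid!r}"
                    )
        for cyc in self.cycles:
            for sid in (cyc.target, cyc.modified_form, cyc.converter):
                if sid not in seen:
                    raise ResolutionError(
                        f"cycle {cyc.id!r} references undeclared species {sid!r}"
                    )
            if cyc.kinase_inhibitor is not None and cyc.kinase_inhibitor not in seen:
                raise ResolutionError(
                    f"cycle {cyc.id!r} references undeclared inhibitor "
                    f"{cyc.kinase_inhibitor!r}"
                )
        uids: set[str] = set()
        for unit in self.gene_units:
            if unit.id in uids:
                raise ConfigurationError(f"duplicate gene unit id {unit.id!r}")
            uids.add(unit.id)
            for pid in unit.member_proteins:
                if pid not in seen:
                    raise ResolutionError(
                        f"gene unit {unit.id!r} references undeclared protein {pid!r}"
                    )
            for reg in unit.regulators:
                if reg.tf not in seen:
                    raise ResolutionError(
                        f"gene unit {unit.id!r} references undeclared TF {reg.tf!r}"
                    )
                if reg.effector is not None and reg.effector not in seen:
                    raise ResolutionError(
                        f"gene unit {unit.id!r} references undeclared effector "
                        f"{reg.effector!r}"
                    )
        for entry in self.biomass:
            if entry.species not in seen:
                raise ResolutionError(
                    f"biomass table references undeclared species {entry.species!r}"
                )

    def _build_matrix(self) -> np.ndarray:
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                S[self.species_index[sid], j] = coeff
        return S

    # -- lookups ------------------------------------------------------------

    def get_species(self, sid: str) -> Species:
        try:
            return self.species[self.species_index[sid]]
        except KeyError:
            raise ResolutionError(f"unknown species {sid!r}") from None

    def get_reaction(self, rid: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == rid:
                return rxn
        raise ResolutionError(f"unknown reaction {rid!r}")

    def get_gene_unit(self, uid: str):
        for unit in self.gene_units:
            if unit.id == uid:
                return unit
        raise ResolutionError(f"unknown gene unit {uid!r}")

    def to_definition(self) -> ModelDefinition:
        return ModelDefinition(
            species=list(self.species),
            reactions=list(self.reactions),
            cycles=list(self.cycles),
            gene_units=list(self.gene_units),
            machinery=self.machinery,
            biomass=list(self.biomass),
        )


def build_network(model_def: ModelDefinition) -> ReactionNetwork:
    """Assemble and validate a :class:`ReactionNetwork` from a definition.

    Auto-creates one mRNA species per gene unit (id ``mRNA_<unit>``) when
    the definition does not declare it.
    """
    species = list(model_def.species)
    ids = {sp.id for sp in species}
    for unit in model_def.gene_units:
        mid = unit.mrna_id
        if mid not in ids:
            species.append(
                Species(id=mid, role="mRNA", concentration=unit.mrna0)
            )
            ids.add(mid)
    return ReactionNetwork(
        species=species,
        reactions=model_def.reactions,
        cycles=model_def.cycles,
        gene_units=model_def.gene_units,
        machinery=model_def.machinery,
        biomass=model_def.biomass,
    )
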