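"""Transcription/translation layer linking gene dosage to enzyme level.

Each :class:`GeneUnit` is an operon-level expression unit: one promoter,
one shared mRNA species, one or more member proteins translated at equal
rates.  The copy factor (X/X0, baseline 1) multiplies the promoter term at
transcription initiation, so in the regulation-free limit steady-state
protein is exactly proportional to gene dosage.

RNA-polymerase and ribosome levels are tabulated against the specific
growth rate mu and interpolated piecewise-linearly (clamped outside the
table); their saturation of the expression machinery is hyperbolic.

Growth dilution (mu) is applied to both mRNA and protein pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ConfigurationError

__all__ = [
    "Regulator",
    "GeneUnit",
    "MachineryProfile",
    "machinery_at",
    "regulator_occupancy",
    "transcription_rate",
    "translation_rate",
    "expression_odes",
]


@dataclass
class Regulator:
    """A transcription-factor binding term on one promoter.

    ``mode`` is ``activator`` or ``repressor``.  An optional small-molecule
    effector modulates the active TF pool: ``effector_role`` is
    ``inactivates`` (effector titrates the TF away, e.g. FDP on Cra, PYR on
    PdhR) or ``activates`` (effector is required for activity, e.g. cAMP on
    CRP).
    """

    tf: str
    mode: str
    K_bind: float
    effector: str | None = None
    K_eff: float | None = None
    effector_role: str = "inactivates"

    def __post_init__(self) -> None:
        if self.mode not in ("activator", "repressor"):
            raise ConfigurationError(f"regulator {self.tf!r}: bad mode {self.mode!r}")
        if self.K_bind <= 0:
            raise ConfigurationError(f"regulator {self.tf!r}: K_bind must be > 0")
        if self.effector is not None and (self.K_eff is None or self.K_eff <= 0):
            raise ConfigurationError(
                f"regulator {self.tf!r}: effector requires K_eff > 0"
            )
        if self.effector_role not in ("inactivates", "activates"):
            raise ConfigurationError(
                f"regulator {self.tf!r}: bad effector_role {self.effector_role!r}"
            )


@dataclass
class GeneUnit:
    """Operon-level expression unit with a dosage multiplier."""

    id: str
    member_proteins: list[str]
    promoter_conc: float = 1.0
    copy_factor: float = 1.0
    k_tx: float = 1.0
    mRNA_deg: float = 0.2
    k_tl: float = 1.0
    protein_deg: float = 0.002
    regulators: list[Regulator] = field(default_factory=list)
    mrna0: float = 0.0
    description: str = ""
    removed: bool = False

    def __post_init__(self) -> None:
        if self.copy_factor < 0:
            raise ConfigurationError(f"gene unit {self.id!r}: copy_factor must be >= 0")
        if not self.member_proteins:
            raise ConfigurationError(f"gene unit {self.id!r}: no member proteins")
        for name in ("promoter_conc", "k_tx", "mRNA_deg", "k_tl", "protein_deg"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"gene unit {self.id!r}: {name} must be >= 0")

    @property
    def mrna_id(self) -> str:
        return f"mRNA_{self.id}"


@dataclass
class MachineryProfile:
    """RNAP and ribosome concentrations as a function of growth rate.

    ``table`` rows are ``(mu [1/min], RNAP_conc, ribosome_conc)`` with mu
    strictly increasing and machinery non-decreasing in mu.  ``K_rnap`` /
    ``K_ribo`` are the hyperbolic half-saturation constants for machinery
    saturation of transcription and translation.
    """

    table: list[tuple[float, float, float]]
    K_rnap: float = 0.002
    K_ribo: float = 0.01
    interpolation: str = "linear"

    def __post_init__(self) -> None:
        if not self.table:
            raise ConfigurationError("machinery profile: empty table")
        mus = [row[0] for row in self.table]
        if any(b <= a for a, b in zip(mus, mus[1:])):
            raise ConfigurationError("machinery profile: mu must be strictly increasing")
        for col in (1, 2):
            vals = [row[col] for row in self.table]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ConfigurationError(
                    "machinery profile: machinery must be non-decreasing in mu"
                )
        if self.K_rnap <= 0 or self.K_ribo <= 0:
            raise ConfigurationError("machinery profile: saturation constants must be > 0")


def machinery_at(profile: MachineryProfile, mu: float) -> tuple[float, float]:
    """Interpolated (RNAP, ribosome) pair at growth rate ``mu``.

    Piecewise linear inside the table, clamped at the endpoints outside.
    """
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    mus = np.array([r[0] for r in profile.table])
    rnap = np.array([r[1] for r in profile.table])
    ribo = np.array([r[2] for r in profile.table])
    return float(np.interp(mu, mus, rnap)), float(np.interp(mu, mus, ribo))


def regulator_occupancy(
    reg: Regulator, tf_conc: float, effector_conc: float | None = None
) -> float:
    """Promoter occupancy multiplier for one regulator, in (0, 1].

    The active TF pool is the total TF scaled by its effector:
    ``inactivates`` -> ``TF / (1 + eff/K_eff)``;
    ``activates``   -> ``TF * eff / (K_eff + eff)``.
    Repressors contribute ``1 / (1 + active/K_bind)``, activators
    ``active / (K_bind + active)``.
    """
    tf_conc = max(tf_conc, 0.0)
    active = tf_conc
    if reg.effector is not None:
        if effector_conc is None:
            raise ConfigurationError(
                f"regulator {reg.tf!r}: missing effector concentration"
            )
        eff = max(effector_conc, 0.0)
        if reg.effector_role == "inactivates":
            active = tf_conc / (1.0 + eff / reg.K_eff)
        else:
            active = tf_conc * eff / (reg.K_eff + eff)
    if reg.mode == "repressor":
        return 1.0 / (1.0 + active / reg.K_bind)
    return active / (reg.K_bind + active)


def _occupancy_product(
    unit: GeneUnit, tf_concs: dict[str, float], effector_concs: dict[str, float]
) -> float:
    occ = 1.0
    for reg in unit.regulators:
        if reg.tf not in tf_concs:
            raise ConfigurationError(
                f"gene unit {unit.id!r}: missing TF concentration {reg.tf!r}"
            )
        eff = None
        if reg.effector is not None:
            if reg.effector not in effector_concs:
                raise ConfigurationError(
                    f"gene unit {unit.id!r}: missing effector {reg.effector!r}"
                )
            eff = effector_concs[reg.effector]
        occ *= regulator_occupancy(reg, tf_concs[reg.tf], eff)
    return occ


def transcription_rate(
    unit: GeneUnit,
    rnap_conc: float,
    tf_concs: dict[str, float] | None = None,
    effector_concs: dict[str, float] | None = None,
    K_rnap: float = 0.002,
) -> float:
    """mRNA synthesis term:
    ``k_tx * promoter * copy_factor * sat(RNAP) * prod(occupancy)``."""
    if unit.removed or unit.copy_factor == 0:
        return 0.0
    sat = max(rnap_conc, 0.0) / (K_rnap + max(rnap_conc, 0.0)) if rnap_conc > 0 else 0.0
    occ = _occupancy_product(unit, tf_concs or {}, effector_concs or {})
    return unit.k_tx * unit.promoter_conc * unit.copy_factor * sat * occ


def translation_rate(
    unit: GeneUnit, mrna_conc: float, ribosome_conc: float, K_ribo: float = 0.01
) -> float:
    """Per-member-protein synthesis term: ``k_tl * mRNA * sat(ribosome)``.

    Identical for every member protein of the operon.
    """
    if mrna_conc < 0:
        raise ValueError(f"mRNA concentration must be >= 0, got {mrna_conc}")
    ribo = max(ribosome_conc, 0.0)
    sat = ribo / (K_ribo + ribo) if ribo > 0 else 0.0
    return unit.k_tl * mrna_conc * sat


def expression_odes(
    unit: GeneUnit,
    state: dict[str, float],
    mu: float,
    machinery: MachineryProfile,
    tf_concs: dict[str, float] | None = None,
    effector_concs: dict[str, float] | None = None,
) -> tuple[float, dict[str, float]]:
    """(d[mRNA]/dt, {protein: d[p]/dt}) for one unit at the given state.

    d[mRNA]/dt = transcription - (mRNA_deg + mu) * [mRNA]
    d[p]/dt    = translation   - (protein_deg + mu) * [p]
    """
    rnap, ribo = machinery_at(machinery, mu)
    m = state[unit.mrna_id]
    dm = (
        transcription_rate(unit, rnap, tf_concs, effector_concs, machinery.K_rnap)
        - (unit.mRNA_deg + mu) * m
    )
    tl = translation_rate(unit, max(m, 0.0), ribo, machinery.K_ribo)
    dp = {
        pid: tl - (unit.protein_deg + mu) * state[pid] for pid in unit.member_proteins
    }
    return dm, dp
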