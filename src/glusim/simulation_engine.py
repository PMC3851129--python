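"""ODE assembly and stiff integration over the fermentation horizon.

The derivative of the state is

    d(state)/dt = S v(state)            (enzymatic reactions)
                + modification fluxes   (ICD phosphorylation cycle)
                + expression terms      (transcription / translation)
                - biomass drains        (composition table x mu(t) X(t))
                - mu(t) * state         (dilution of intracellular pools)

Growth is prescribed: mu(t) is derived from a tabulated biomass-density
profile X(t) (piecewise linear), so growth is an input of the simulation,
not an output.  Extracellular pools are not diluted, and boundary species
are clamped.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import ConfigurationError, ReactionNetwork, ResolutionError

__all__ = [
    "GrowthProfile",
    "GrowthInfeasibleError",
    "SimulationConfig",
    "TimeCourse",
    "SimulationError",
    "assemble_odes",
    "simulate",
    "knockout",
    "apply_copy_factor",
    "yield_metric",
]

log = logging.getLogger(__name__)


class SimulationError(RuntimeError):
    """Integration failed or produced an inadmissible trajectory."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class GrowthInfeasibleError(SimulationError):
    """The perturbed model cannot feed the prescribed growth profile."""


@dataclass
class GrowthProfile:
    """Tabulated biomass density X(t) with derived mu(t) = (dX/dt)/X."""

    times: np.ndarray  # min, strictly increasing
    densities: np.ndarray  # g/L, > 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.times.size < 2:
            raise ConfigurationError("growth profile needs at least two points")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("growth profile times must be strictly increasing")
        if np.any(self.densities <= 0):
            raise ConfigurationError("growth profile densities must be > 0")
        self._slopes = np.diff(self.densities) / np.diff(self.times)

    def X_at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.densities))

    def mu_at(self, t: float) -> float:
        """Specific growth rate from the piecewise-linear density.

        Clamped to the first/last segment slope outside the table; the
        right-hand slope is used at interior knots.
        """
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        idx = min(max(idx, 0), len(self._slopes) - 1)
        return float(self._slopes[idx] / self.X_at(t))

    @property
    def t_max(self) -> float:
        return float(self.times[-1])


@dataclass
class SimulationConfig:
    t_end: float = 840.0
    output_interval: float = 5.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    solver: str = "BDF"
    seed: int | None = None  # reserved; runs are deterministic
    yield_basis: str = "molar"  # or "titer"
    negative_tolerance: float = 1e-6
    # biomass drains shut off smoothly below this pool size (mM) so that
    # starving perturbations yield poor-but-finite trajectories instead of
    # negative pools; at healthy pool sizes (>= 0.01 mM) the relative
    # deviation from the exact drain is < 1e-8 (pools >= 1e-3 mM)
    drain_softening: float = 1e-5
    # growth is prescribed: if softened drains fall short of the exact
    # biomass demand by more than this relative tolerance, the perturbed
    # model cannot sustain the required growth and the run is infeasible
    growth_integrity_tolerance: float | None = 0.01
    fed_glucose: float = 0.0  # mM added over the run, for the yield basis
    # when the glucose pool is clamped (continuous feed), consumption is
    # metered exactly through an inert counter species produced 1:1 by the
    # uptake reaction, or (less accurately) by integrating an uptake flux
    consumption_species: str | None = None
    uptake_reaction: str | None = None

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ConfigurationError("t_end must be > 0")
        n = self.t_end / self.output_interval
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("output_interval must divide t_end")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.t_end / self.output_interval))
        return np.linspace(0.0, self.t_end, n + 1)


@dataclass
class TimeCourse:
    """State and flux trajectories on the uniform output grid."""

    time: np.ndarray  # (T,)
    states: np.ndarray  # (n_species, T)
    fluxes: np.ndarray  # (n_reactions, T)
    species_ids: list[str]
    reaction_ids: list[str]
    config: SimulationConfig | None = None

    def series(self, species_id: str) -> np.ndarray:
        try:
            return self.states[self.species_ids.index(species_id)]
        except ValueError:
            raise ResolutionError(f"unknown species {species_id!r}") from None

    def flux_series(self, reaction_id: str) -> np.ndarray:
        try:
            return self.fluxes[self.reaction_ids.index(reaction_id)]
        except ValueError:
            raise ResolutionError(f"unknown reaction {reaction_id!r}") from None

    def final(self, species_id: str) -> float:
        return float(self.series(species_id)[-1])


# ---------------------------------------------------------------------------
# compiled right-hand side


class _CompiledSystem:
    """Index-based evaluator for the full ODE right-hand side.

    Everything is resolved to integer indices once so that per-call work is
    plain float arithmetic; this keeps stiff integration of the reference
    model well under a second per run.
    """

    def __init__(self, network: ReactionNetwork, profile, biomass_table,
                 drain_softening: float = 1e-5):
        self.network = network
        self.profile = profile
        self.drain_softening = float(drain_softening)
        idx = network.species_index
        n = len(network.species)
        self.n = n
        self.boundary = np.array(
            [sp.role == "boundary" for sp in network.species], dtype=bool
        )
        # dilution applies to intracellular, non-boundary metabolite pools;
        # mRNA/protein dilution is handled inside the expression terms
        self.dilute = np.array(
            [
                sp.compartment == "intracellular"
                and sp.role == "metabolite"
                and not self.boundary[i]
                for i, sp in enumerate(network.species)
            ],
            dtype=bool,
        )
        self.y0_full = np.array([sp.concentration for sp in network.species])
        # only dynamic (non-boundary) species are integrated; clamped pools
        # are baked into the generated code as constants
        self.dyn = np.flatnonzero(~self.boundary)
        self.dyn_index = {int(i): d for d, i in enumerate(self.dyn)}
        self.y0 = self.y0_full[self.dyn]

        # reactions
        self.rxns = []
        for j, rxn in enumerate(network.reactions):
            law = rxn.rate_law
            subs = [(idx[s], law.Km[s]) for s in law.substrates if s in law.Km]
            prods = [(idx[s], law.Km[s]) for s in law.products if s in law.Km]
            ma_subs = (
                [(idx[s], law.orders.get(s, 1.0)) for s in law.substrates]
                if law.form == "mass_action"
                else []
            )
            inh = [(idx[s], ki) for s, ki, _m in law.inhibitors]
            mods = [(idx[s], k) for s, k in law.modifiers]
            cat = idx[rxn.catalyst] if rxn.catalyst else -1
            stoich = [(idx[s], c) for s, c in rxn.stoichiometry.items()]
            self.rxns.append(
                (law.form, law.kcat, law.Keq, subs, prods, ma_subs, inh, mods, cat, stoich)
            )

        # modification cycles
        self.cycles = []
        for cyc in network.cycles:
            self.cycles.append(
                (
                    idx[cyc.target],
                    idx[cyc.modified_form],
                    idx[cyc.converter],
                    cyc.k_kin,
                    cyc.k_phos,
                    cyc.Km_kin,
                    cyc.Km_phos,
                    idx[cyc.kinase_inhibitor] if cyc.kinase_inhibitor else -1,
                    cyc.Ki_inh if cyc.Ki_inh else 1.0,
                )
            )

        # gene units
        mach = network.machinery
        self.mach = mach
        self.units = []
        for unit in network.gene_units:
            regs = []
            for reg in unit.regulators:
                regs.append(
                    (
                        idx[reg.tf],
                        reg.mode == "repressor",
                        reg.K_bind,
                        idx[reg.effector] if reg.effector else -1,
                        reg.K_eff if reg.K_eff else 1.0,
                        reg.effector_role == "inactivates",
                    )
                )
            self.units.append(
                (
                    idx[unit.mrna_id],
                    [idx[p] for p in unit.member_proteins],
                    0.0
                    if (unit.removed or unit.copy_factor == 0)
                    else unit.k_tx * unit.promoter_conc * unit.copy_factor,
                    unit.mRNA_deg,
                    unit.k_tl,
                    unit.protein_deg,
                    regs,
                )
            )
        if self.units and mach is None:
            raise ConfigurationError("network has gene units but no machinery profile")

        # biomass drains
        self.drains = []
        for entry in biomass_table or []:
            if entry.species not in idx:
                raise ResolutionError(
                    f"biomass table references unknown species {entry.species!r}"
                )
            i = idx[entry.species]
            if self.boundary[i]:
                raise ConfigurationError(
                    f"biomass table drains boundary species {entry.species!r}"
                )
            self.drains.append((i, entry.coefficient))

        # machinery knots for fast interpolation
        if mach is not None:
            self._mach_mu = np.array([r[0] for r in mach.table])
            self._mach_rnap = np.array([r[1] for r in mach.table])
            self._mach_ribo = np.array([r[2] for r in mach.table])

        self._rhs_fast = self._codegen()
        self.jac_sparsity = self._sparsity()
        self._jac_groups = self._color_columns(self.jac_sparsity)

    def expand_state(self, y_dyn: np.ndarray) -> np.ndarray:
        """Full species-ordered state from a dynamic-state vector."""
        full = self.y0_full.copy()
        full[self.dyn] = y_dyn
        return full

    def _sparsity(self) -> np.ndarray:
        """Boolean dependency pattern of d(dy_i)/d(y_j) over the dynamic
        states, used for the colored finite-difference Jacobian."""
        pat = np.zeros((self.n, self.n), dtype=bool)

        def couple(targets: list[int], sources: list[int]) -> None:
            for i in targets:
                if not self.boundary[i]:
                    pat[i, sources] = True

        for form, _k, _q, subs, prods, ma_subs, inh, mods, cat, stoich in self.rxns:
            deps = [i for i, _ in subs] + [i for i, _ in prods]
            deps += [i for i, _ in ma_subs]
            deps += [i for i, _ in inh] + [i for i, _ in mods]
            if cat >= 0:
                deps.append(cat)
            couple([i for i, _ in stoich], deps)
        for tgt, mod, conv, *_rest, inh_i, _ki in self.cycles:
            deps = [tgt, mod, conv] + ([inh_i] if inh_i >= 0 else [])
            couple([tgt, mod], deps)
        for m_i, p_is, _tx0, _md, _ktl, _pd, regs in self.units:
            deps = [m_i]
            for tf_i, _r, _kb, eff_i, _ke, _in in regs:
                deps.append(tf_i)
                if eff_i >= 0:
                    deps.append(eff_i)
            couple([m_i], deps)
            for p_i in p_is:
                couple([p_i], [m_i, p_i])
        pat = pat[np.ix_(self.dyn, self.dyn)]
        np.fill_diagonal(pat, True)
        return pat

    @staticmethod
    def _color_columns(pat: np.ndarray) -> list[np.ndarray]:
        """Greedy column coloring: columns sharing a claimed row never land
        in the same group, so one perturbed evaluation serves a whole group."""
        n = pat.shape[1]
        cols = pat.T.astype(bool)
        groups: list[list[int]] = []
        group_rows: list[np.ndarray] = []
        for j in range(n):
            placed = False
            for g, rows in enumerate(group_rows):
                if not np.any(rows & cols[j]):
                    groups[g].append(j)
                    group_rows[g] = rows | cols[j]
                    placed = True
                    break
            if not placed:
                groups.append([j])
                group_rows.append(cols[j].copy())
        return [np.array(g, dtype=int) for g in groups]

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        """Colored finite-difference Jacobian of the dynamic system."""
        f0 = self._rhs_fast(t, y)
        n = y.size
        J = np.zeros((n, n))
        pat = self.jac_sparsity
        for group in self._jac_groups:
            h = 1e-8 + 1e-7 * np.abs(y[group])
            yp = y.copy()
            yp[group] += h
            df = self._rhs_fast(t, yp) - f0
            for j, hj in zip(group, h):
                rows = pat[:, j]
                J[rows, j] = df[rows] / hj
        return J

    # -- code generation ----------------------------------------------------
    #
    # The right-hand side is evaluated tens of thousands of times per stiff
    # integration, so it is emitted once as fully unrolled scalar Python
    # (every index and constant baked in) instead of interpreting the
    # reaction list on every call.  All rate expressions are branchless:
    # concentrations are clamped at zero through max().

    def _codegen(self):
        lines: list[str] = []
        emit = lines.append
        used: set[int] = set()
        dy_terms: dict[int, list[str]] = {i: [] for i in range(self.n)}

        def yv(i: int) -> str:
            used.add(i)
            return f"y{i}"

        def pos(i: int) -> str:
            return f"max({yv(i)}, 0.0)"

        flux_exprs: list[str] = []
        for j, (form, kcat, keq, subs, prods, ma_subs, inh, mods, cat, stoich) in enumerate(
            self.rxns
        ):
            parts = [repr(kcat)]
            if cat >= 0:
                parts.append(pos(cat))
            for i, ki in inh:
                parts.append(f"({ki!r} / ({ki!r} + {pos(i)}))")
            for i, k in mods:
                m = pos(i)
                parts.append(f"({m} / ({k!r} + {m}))")
            if form == "irreversible_mm":
                for i, km in subs:
                    s = pos(i)
                    parts.append(f"({s} / ({km!r} + {s}))")
                expr = " * ".join(parts)
            elif form == "mass_action":
                for i, order in ma_subs:
                    parts.append(
                        pos(i) if order == 1.0 else f"{pos(i)}**{order!r}"
                    )
                expr = " * ".join(parts)
            else:  # reversible_mm
                fwd = " * ".join(pos(i) for i, _ in subs) or "1.0"
                rev = " * ".join(pos(i) for i, _ in prods) or "1.0"
                km_s = 1.0
                den_terms = []
                for i, km in subs:
                    km_s *= km
                    den_terms.append(f"(1.0 + {pos(i)} / {km!r})")
                den_s = " * ".join(den_terms) or "1.0"
                den_terms = [f"(1.0 + {pos(i)} / {km!r})" for i, km in prods]
                den_p = " * ".join(den_terms) or "1.0"
                expr = (
                    f"{' * '.join(parts)} * (({fwd}) - ({rev}) / {keq!r}) "
                    f"/ ({km_s!r} * (({den_s}) + ({den_p}) - 1.0))"
                )
            emit(f"    v{j} = {expr}")
            flux_exprs.append(f"v{j}")
            for i, c in stoich:
                dy_terms[i].append(f"{c!r} * v{j}")

        for c_idx, (tgt, mod, conv, k_kin, k_phos, km_k, km_p, inh_i, ki) in enumerate(
            self.cycles
        ):
            e, tg, md = pos(conv), pos(tgt), pos(mod)
            f_inh = f"({ki!r} / ({ki!r} + {pos(inh_i)}))" if inh_i >= 0 else "1.0"
            emit(
                f"    cyc{c_idx} = {k_kin!r} * {e} * {f_inh} * {tg} / ({km_k!r} + {tg})"
                f" - {k_phos!r} * {e} * {md} / ({km_p!r} + {md})"
            )
            dy_terms[tgt].append(f"-cyc{c_idx}")
            dy_terms[mod].append(f"cyc{c_idx}")

        if self.units:
            emit("    rnap = interp(mu, mach_mu, mach_rnap)")
            emit("    ribo = interp(mu, mach_mu, mach_ribo)")
            emit(f"    sat_rnap = rnap / ({self.mach.K_rnap!r} + rnap)")
            emit(f"    sat_ribo = ribo / ({self.mach.K_ribo!r} + ribo)")
            for u_idx, (m_i, p_is, tx0, mdeg, ktl, pdeg, regs) in enumerate(self.units):
                occ_parts = []
                for tf_i, is_rep, kb, eff_i, keff, inact in regs:
                    active = pos(tf_i)
                    if eff_i >= 0:
                        eff = pos(eff_i)
                        if inact:
                            active = f"({active} / (1.0 + {eff} / {keff!r}))"
                        else:
                            active = f"({active} * {eff} / ({keff!r} + {eff}))"
                    if is_rep:
                        occ_parts.append(f"(1.0 / (1.0 + {active} / {kb!r}))")
                    else:
                        occ_parts.append(f"({active} / ({kb!r} + {active}))")
                occ = " * ".join(occ_parts) if occ_parts else "1.0"
                dy_terms[m_i].append(
                    f"{tx0!r} * sat_rnap * {occ} - ({mdeg!r} + mu) * {yv(m_i)}"
                )
                emit(f"    tl{u_idx} = {ktl!r} * {pos(m_i)} * sat_ribo")
                for p_i in p_is:
                    dy_terms[p_i].append(f"tl{u_idx} - ({pdeg!r} + mu) * {yv(p_i)}")

        eps4 = self.drain_softening**4
        for k, (i, coeff) in enumerate(self.drains):
            emit(f"    s4_{k} = {pos(i)}**4")
            dy_terms[i].append(f"-{coeff!r} * muX * s4_{k} / (s4_{k} + {eps4!r})")

        for i in range(self.n):
            if self.dilute[i]:
                dy_terms[i].append(f"-mu * {yv(i)}")

        dy_exprs = []
        for i in self.dyn:
            if not dy_terms[i]:
                dy_exprs.append("0.0")
            else:
                dy_exprs.append(" + ".join(dy_terms[i]).replace("+ -", "- "))

        header = ["def _rhs(t, y):"]
        if self.profile is not None:
            header += [
                "    k = searchsorted(prof_t, t, 'right') - 1",
                f"    k = 0 if k < 0 else ({len(self.profile._slopes) - 1} if k > "
                f"{len(self.profile._slopes) - 1} else k)",
                "    X = prof_X[k] + prof_s[k] * (t - prof_t[k])",
                "    mu = prof_s[k] / X",
                "    mu = mu if mu > 0.0 else 0.0",
                "    muX = mu * X",
            ]
        else:
            header += ["    mu = 0.0", "    muX = 0.0"]
        loads = [
            (
                f"    y{i} = y[{self.dyn_index[i]}]"
                if i in self.dyn_index
                else f"    y{i} = {float(self.y0_full[i])!r}"  # clamped boundary pool
            )
            for i in sorted(used)
        ]
        body = (
            header
            + loads
            + lines
            + ["    return array([", *(f"        {e}," for e in dy_exprs), "    ])"]
        )
        src = "\n".join(body)
        ns: dict = {
            "array": np.array,
            "searchsorted": np.searchsorted,
            "interp": np.interp,
            "max": max,
        }
        if self.profile is not None:
            ns["prof_t"] = self.profile.times
            ns["prof_X"] = self.profile.densities
            ns["prof_s"] = self.profile._slopes
        if self.units:
            ns["mach_mu"] = self._mach_mu
            ns["mach_rnap"] = self._mach_rnap
            ns["mach_ribo"] = self._mach_ribo
        exec(compile(src, "<glusim-rhs>", "exec"), ns)
        return ns["_rhs"]

    # -- flux evaluation ----------------------------------------------------

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        v = np.empty(len(self.rxns))
        for j, (form, kcat, keq, subs, prods, ma_subs, inh, mods, cat, _st) in enumerate(
            self.rxns
        ):
            e = y[cat] if cat >= 0 else 1.0
            if e <= 0.0:
                v[j] = 0.0
                continue
            reg = 1.0
            for i, ki in inh:
                c = y[i]
                if c > 0.0:
                    reg *= ki / (ki + c)
            for i, k in mods:
                c = y[i]
                reg = reg * c / (k + c) if c > 0.0 else 0.0
            if form == "irreversible_mm":
                r = kcat * e * reg
                for i, km in subs:
                    s = y[i]
                    r = r * s / (km + s) if s > 0.0 else 0.0
                v[j] = r
            elif form == "reversible_mm":
                fwd = 1.0
                den_s = 1.0
                km_s = 1.0
                for i, km in subs:
                    s = max(y[i], 0.0)
                    km_s *= km
                    fwd *= s
                    den_s *= 1.0 + s / km
                rev = 1.0 / keq
                den_p = 1.0
                for i, km in prods:
                    pc = max(y[i], 0.0)
                    rev *= pc
                    den_p *= 1.0 + pc / km
                v[j] = kcat * e * reg * (fwd - rev) / (km_s * (den_s + den_p - 1.0))
            else:  # mass_action
                r = kcat * e * reg
                for i, order in ma_subs:
                    s = y[i]
                    r = r * s**order if s > 0.0 else 0.0
                v[j] = r
        return v

    # -- right-hand side ----------------------------------------------------

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self._rhs_fast(t, y)

    def rhs_reference(self, t: float, y: np.ndarray) -> np.ndarray:
        """Interpreted evaluation of the same derivative (used to validate
        the generated code and by small diagnostic runs)."""
        dy = np.zeros(self.n)
        mu = self.profile.mu_at(t) if self.profile is not None else 0.0
        mu = max(mu, 0.0)
        X = self.profile.X_at(t) if self.profile is not None else 0.0

        v = self.fluxes(y)
        for j, rc in enumerate(self.rxns):
            vj = v[j]
            if vj != 0.0:
                for i, c in rc[9]:
                    dy[i] += c * vj

        for tgt, mod, conv, k_kin, k_phos, km_k, km_p, inh_i, ki in self.cycles:
            e = max(y[conv], 0.0)
            tg = max(y[tgt], 0.0)
            md = max(y[mod], 0.0)
            f_inh = ki / (ki + max(y[inh_i], 0.0)) if inh_i >= 0 else 1.0
            kin = k_kin * e * f_inh * tg / (km_k + tg)
            phos = k_phos * e * md / (km_p + md)
            net = kin - phos
            dy[tgt] -= net
            dy[mod] += net

        if self.units:
            rnap = float(np.interp(mu, self._mach_mu, self._mach_rnap))
            ribo = float(np.interp(mu, self._mach_mu, self._mach_ribo))
            sat_rnap = rnap / (self.mach.K_rnap + rnap)
            sat_ribo = ribo / (self.mach.K_ribo + ribo)
            for m_i, p_is, tx0, mdeg, ktl, pdeg, regs in self.units:
                occ = 1.0
                for tf_i, is_rep, kb, eff_i, keff, inact in regs:
                    active = max(y[tf_i], 0.0)
                    if eff_i >= 0:
                        eff = max(y[eff_i], 0.0)
                        if inact:
                            active = active / (1.0 + eff / keff)
                        else:
                            active = active * eff / (keff + eff)
                    occ *= 1.0 / (1.0 + active / kb) if is_rep else active / (kb + active)
                m = y[m_i]
                dy[m_i] += tx0 * sat_rnap * occ - (mdeg + mu) * m
                tl = ktl * max(m, 0.0) * sat_ribo
                for p_i in p_is:
                    dy[p_i] += tl - (pdeg + mu) * y[p_i]

        if self.drains and X > 0.0 and mu > 0.0:
            rate = mu * X
            eps4 = self.drain_softening**4
            for i, coeff in self.drains:
                s4 = max(y[i], 0.0) ** 4
                dy[i] -= coeff * rate * s4 / (s4 + eps4)

        dy[self.dilute] -= mu * y[self.dilute]
        dy[self.boundary] = 0.0
        return dy


def assemble_odes(
    network: ReactionNetwork,
    growth_profile: GrowthProfile | None,
    biomass_table=None,
    t_end: float | None = None,
    drain_softening: float = 1e-5,
):
    """Build the derivative function f(t, y) for the full system.

    The growth profile must cover the horizon when one is given; pass
    ``None`` for closed systems with no growth.
    """
    if growth_profile is not None and t_end is not None:
        if growth_profile.t_max < t_end:
            raise ConfigurationError(
                f"growth profile ends at {growth_profile.t_max} min, "
                f"shorter than the {t_end} min horizon"
            )
    system = _CompiledSystem(network, growth_profile, biomass_table, drain_softening)
    return system


def simulate(
    network: ReactionNetwork,
    profile: GrowthProfile | None = None,
    config: SimulationConfig | None = None,
    biomass_table=None,
) -> TimeCourse:
    """Integrate the network over the configured horizon.

    Returns the trajectory sampled on the exact uniform output grid
    (t_end / output_interval + 1 points).  Deterministic for fixed inputs
    and tolerances.
    """
    config = config or SimulationConfig()
    if biomass_table is None:
        biomass_table = network.biomass
    system = assemble_odes(
        network,
        profile,
        biomass_table,
        t_end=config.t_end,
        drain_softening=config.drain_softening,
    )
    grid = config.grid
    log.info(
        "simulate: horizon=%g min, %d species, %d reactions, solver=%s",
        config.t_end,
        system.n,
        len(network.reactions),
        config.solver,
    )
    kwargs = {}
    if config.solver in ("BDF", "Radau"):
        kwargs["jac"] = system.jacobian
    sol = solve_ivp(
        system.rhs,
        (0.0, config.t_end),
        system.y0,
        method=config.solver,
        t_eval=grid,
        rtol=config.rel_tol,
        atol=config.abs_tol,
        **kwargs,
    )
    if not sol.success or sol.t.size != grid.size:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise SimulationError(
            f"integration failed at t={last:g} min: {sol.message}", last_time=last
        )
    worst = sol.y.min(axis=1)
    bad = np.where(worst < -config.negative_tolerance)[0]
    if bad.size:
        names = ", ".join(network.species[system.dyn[i]].id for i in bad[:5])
        raise SimulationError(
            f"negative concentrations beyond tolerance for: {names} "
            f"(min {worst[bad].min():.3g})"
        )
    _check_growth_integrity(system, sol, grid, config, profile, biomass_table)
    # reassemble the full species-ordered state matrix (boundary rows constant)
    states = np.repeat(system.y0_full[:, None], grid.size, axis=1)
    states[system.dyn, :] = sol.y
    fluxes = np.empty((len(network.reactions), grid.size))
    for k in range(grid.size):
        fluxes[:, k] = system.fluxes(states[:, k])
    log.info("simulate: done, %d output points, %d rhs evaluations", grid.size, sol.nfev)
    return TimeCourse(
        time=grid,
        states=states,
        fluxes=fluxes,
        species_ids=[sp.id for sp in network.species],
        reaction_ids=[r.id for r in network.reactions],
        config=config,
    )


def _check_growth_integrity(system, sol, grid, config, profile, biomass_table):
    """Fail the run when drain softening withheld a material share of the
    prescribed biomass demand (the growth profile is an input, so a model
    that cannot feed it is infeasible rather than merely low-yield)."""
    tol = config.growth_integrity_tolerance
    if tol is None or not biomass_table or profile is None:
        return
    muX = np.array([max(profile.mu_at(t), 0.0) * profile.X_at(t) for t in grid])
    eps4 = config.drain_softening**4
    exact_total = 0.0
    actual_total = 0.0
    for i, coeff in system.drains:
        if coeff <= 0:
            continue
        s = np.maximum(sol.y[system.dyn_index[i]], 0.0)
        soft = s**4 / (s**4 + eps4)
        exact_total += coeff * np.trapezoid(muX, grid)
        actual_total += coeff * np.trapezoid(muX * soft, grid)
    if exact_total > 0 and (exact_total - actual_total) / exact_total > tol:
        raise GrowthInfeasibleError(
            "prescribed growth infeasible: biomass drains fell short by "
            f"{100 * (exact_total - actual_total) / exact_total:.1f}%"
        )


def knockout(network: ReactionNetwork, gene_unit_id: str) -> ReactionNetwork:
    """Return a copy of the network with one gene unit removed.

    The unit's synthesis is silenced and its member proteins (and mRNA)
    start at zero, so every reaction they catalyse carries zero flux.
    Knocking out an already-removed unit is a no-op with a warning.
    """
    net = copy.deepcopy(network)
    unit = net.get_gene_unit(gene_unit_id)
    if unit.removed:
        warnings.warn(f"gene unit {gene_unit_id!r} is already removed", stacklevel=2)
        return net
    unit.removed = True
    unit.mrna0 = 0.0
    for sid in list(unit.member_proteins) + [unit.mrna_id]:
        if sid in net.species_index:
            net.get_species(sid).concentration = 0.0
    return net


def apply_copy_factor(
    network: ReactionNetwork, gene_unit_id: str, factor: float
) -> ReactionNetwork:
    """Return a copy with one unit's copy factor multiplied by ``factor``."""
    if factor <= 0:
        raise ValueError(f"copy factor must be > 0, got {factor}")
    net = copy.deepcopy(network)
    unit = net.get_gene_unit(gene_unit_id)
    unit.copy_factor *= factor
    return net


def yield_metric(
    tc: TimeCourse,
    product_id: str = "GLUxt",
    glucose_id: str = "GLCxt",
    basis: str | None = None,
) -> float:
    """Product yield over the run.

    ``molar`` basis (default): mol glutamate secreted per mol glucose
    consumed, ``(GLUxt(end) - GLUxt(0)) / (GLCxt(0) + fed - GLCxt(end))``.
    When the glucose pool is clamped (continuous feed), set
    ``config.uptake_reaction`` and consumption is the time integral of that
    uptake flux instead.  ``titer`` basis: final extracellular product
    concentration.
    """
    cfg = tc.config or SimulationConfig()
    basis = basis or cfg.yield_basis
    prod = tc.series(product_id)
    if basis == "titer":
        return float(prod[-1])
    if cfg.consumption_species is not None:
        counter = tc.series(cfg.consumption_species)
        consumed = float(counter[-1] - counter[0])
    elif cfg.uptake_reaction is not None:
        consumed = float(
            np.trapezoid(tc.flux_series(cfg.uptake_reaction), tc.time)
        )
    else:
        glc = tc.series(glucose_id)
        consumed = float(glc[0] - glc[-1] + cfg.fed_glucose)
    if consumed <= 0:
        raise SimulationError("no glucose consumed over the run; yield undefined")
    return float(prod[-1] - prod[0]) / consumed
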