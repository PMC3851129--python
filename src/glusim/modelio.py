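"""Readers and writers for the model-definition format and tabular outputs.

Model-definition grammar (line oriented, ``#`` comments, blank lines
ignored; units are mM and 1/min throughout):

``[species]`` rows::

    <id> <role> <compartment> <concentration>

``[reactions]`` rows::

    <id>: <stoichiometry> | key=value ...

where the stoichiometry is ``2 A + B -> C + 3 D`` (coefficients optional,
default 1) and the keys are ``form`` (irreversible_mm | reversible_mm |
mass_action), ``catalyst``, ``kcat``, ``Keq``, ``Km.<species>``,
``inh.<species>`` (Ki), ``mod.<species>`` (half-saturation of a saturating
activator).

``[cycles]`` rows::

    <id>: target=.. modified=.. converter=.. k_kin=.. k_phos=..
          Km_kin=.. Km_phos=.. [inhibitor=.. Ki=..]

``[genes]`` rows::

    <id>: proteins=P1,P2 promoter=.. copy=.. k_tx=.. mrna_deg=.. k_tl=..
          protein_deg=.. mrna0=.. [desc="..."]
          [reg=TF:mode:K_bind[:effector:K_eff:effector_role]]...

``[machinery]``: ``K_rnap``/``K_ribo`` assignments plus data rows
``<mu> <RNAP> <ribosome>``.

``[biomass]`` rows: ``<species> <mmol_per_g>``.

Growth profiles and time courses are plain TSV.
"""

from __future__ import annotations

import hashlib
import json
import shlex
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .biomass_model import PrecursorCoefficient
from .gene_expression import GeneUnit, MachineryProfile, Regulator
from .model_core import (
    ConfigurationError,
    ModelDefinition,
    ModificationCycle,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
)
from .simulation_engine import GrowthProfile, TimeCourse

__all__ = [
    "ModelSyntaxError",
    "read_model",
    "write_model",
    "read_growth_profile",
    "write_growth_profile",
    "read_timecourse",
    "write_timecourse",
    "model_checksum",
]

SECTIONS = ("species", "reactions", "cycles", "genes", "machinery", "biomass")


class ModelSyntaxError(ConfigurationError):
    """Malformed model file; carries the offending line number."""

    def __init__(self, message: str, path, lineno: int):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _parse_stoichiometry(text: str, path, lineno: int) -> dict[str, float]:
    if "->" not in text:
        raise ModelSyntaxError("stoichiometry must contain '->'", path, lineno)
    left, right = text.split("->", 1)
    stoich: dict[str, float] = {}

    def side(expr: str, sign: float) -> None:
        expr = expr.strip()
        if not expr:
            return
        for term in expr.split("+"):
            parts = term.split()
            if len(parts) == 1:
                coeff, sid = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError:
                    raise ModelSyntaxError(
                        f"bad coefficient {parts[0]!r}", path, lineno
                    ) from None
                sid = parts[1]
            else:
                raise ModelSyntaxError(f"bad term {term.strip()!r}", path, lineno)
            stoich[sid] = stoich.get(sid, 0.0) + sign * coeff
    side(left, -1.0)
    side(right, +1.0)
    return {s: c for s, c in stoich.items() if c != 0}


def _parse_kv(tokens: list[str], path, lineno: int) -> list[tuple[str, str]]:
    pairs = []
    for tok in tokens:
        if "=" not in tok:
            raise ModelSyntaxError(f"expected key=value, got {tok!r}", path, lineno)
        k, v = tok.split("=", 1)
        pairs.append((k, v))
    return pairs


def _parse_regulator(text: str, path, lineno: int) -> Regulator:
    parts = text.split(":")
    if len(parts) not in (3, 6):
        raise ModelSyntaxError(
            "regulator must be TF:mode:K_bind[:effector:K_eff:role]", path, lineno
        )
    try:
        if len(parts) == 3:
            return Regulator(tf=parts[0], mode=parts[1], K_bind=float(parts[2]))
        return Regulator(
            tf=parts[0],
            mode=parts[1],
            K_bind=float(parts[2]),
            effector=parts[3],
            K_eff=float(parts[4]),
            effector_role=parts[5],
        )
    except (ValueError, ConfigurationError) as exc:
        raise ModelSyntaxError(f"bad regulator {text!r}: {exc}", path, lineno) from None


def read_model(path) -> ModelDefinition:
    """Parse a model-definition file into a :class:`ModelDefinition`.

    Errors carry the file name and line number of the offender.
    """
    path = Path(path)
    defn = ModelDefinition()
    mach_rows: list[tuple[float, float, float]] = []
    mach_params: dict[str, float] = {}
    section = None
    seen_species: dict[str, int] = {}
    seen_reactions: dict[str, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip()
            if section not in SECTIONS:
                raise ModelSyntaxError(f"unknown section {section!r}", path, lineno)
            continue
        if section is None:
            raise ModelSyntaxError("content before first section", path, lineno)
        try:
            if section == "species":
                parts = line.split()
                if len(parts) != 4:
                    raise ModelSyntaxError(
                        "species row needs: id role compartment concentration",
                        path,
                        lineno,
                    )
                sid = parts[0]
                if sid in seen_species:
                    raise ModelSyntaxError(
                        f"duplicate species {sid!r} (first at line "
                        f"{seen_species[sid]})",
                        path,
                        lineno,
                    )
                seen_species[sid] = lineno
                defn.species.append(
                    Species(
                        id=sid,
                        role=parts[1],
                        compartment=parts[2],
                        concentration=float(parts[3]),
                    )
                )
            elif section == "reactions":
                rid, rest = line.split(":", 1)
                rid = rid.strip()
                if rid in seen_reactions:
                    raise ModelSyntaxError(
                        f"duplicate reaction {rid!r} (first at line "
                        f"{seen_reactions[rid]})",
                        path,
                        lineno,
                    )
                seen_reactions[rid] = lineno
                if "|" not in rest:
                    raise ModelSyntaxError(
                        "reaction needs '| key=value ...' part", path, lineno
                    )
                stoich_text, kv_text = rest.split("|", 1)
                stoich = _parse_stoichiometry(stoich_text, path, lineno)
                form, kcat, keq, catalyst = "irreversible_mm", 1.0, None, None
                km: dict[str, float] = {}
                inhibitors: list[tuple[str, float, str]] = []
                modifiers: list[tuple[str, float]] = []
                for k, v in _parse_kv(shlex.split(kv_text), path, lineno):
                    if k == "form":
                        form = v
                    elif k == "catalyst":
                        catalyst = v
                    elif k == "kcat":
                        kcat = float(v)
                    elif k == "Keq":
                        keq = float(v)
                    elif k.startswith("Km."):
                        km[k[3:]] = float(v)
                    elif k.startswith("inh."):
                        inhibitors.append((k[4:], float(v), "noncompetitive"))
                    elif k.startswith("mod."):
                        modifiers.append((k[4:], float(v)))
                    else:
                        raise ModelSyntaxError(f"unknown key {k!r}", path, lineno)
                defn.reactions.append(
                    Reaction(
                        id=rid,
                        stoichiometry=stoich,
                        catalyst=catalyst,
                        rate_law=RateLaw(
                            form=form,
                            kcat=kcat,
                            Km=km,
                            Keq=keq,
                            inhibitors=inhibitors,
                            modifiers=modifiers,
                        ),
                    )
                )
            elif section == "cycles":
                cid, rest = line.split(":", 1)
                kv = dict(_parse_kv(shlex.split(rest), path, lineno))
                defn.cycles.append(
                    ModificationCycle(
                        id=cid.strip(),
                        target=kv["target"],
                        modified_form=kv["modified"],
                        converter=kv["converter"],
                        k_kin=float(kv["k_kin"]),
                        k_phos=float(kv["k_phos"]),
                        Km_kin=float(kv.get("Km_kin", 1.0)),
                        Km_phos=float(kv.get("Km_phos", 1.0)),
                        kinase_inhibitor=kv.get("inhibitor"),
                        Ki_inh=float(kv["Ki"]) if "Ki" in kv else None,
                    )
                )
            elif section == "genes":
                uid, rest = line.split(":", 1)
                regulators = []
                kv: dict[str, str] = {}
                for k, v in _parse_kv(shlex.split(rest), path, lineno):
                    if k == "reg":
                        regulators.append(_parse_regulator(v, path, lineno))
                    else:
                        kv[k] = v
                defn.gene_units.append(
                    GeneUnit(
                        id=uid.strip(),
                        member_proteins=kv["proteins"].split(","),
                        promoter_conc=float(kv.get("promoter", 1.0)),
                        copy_factor=float(kv.get("copy", 1.0)),
                        k_tx=float(kv["k_tx"]),
                        mRNA_deg=float(kv.get("mrna_deg", 0.2)),
                        k_tl=float(kv.get("k_tl", 1.0)),
                        protein_deg=float(kv.get("protein_deg", 0.002)),
                        mrna0=float(kv.get("mrna0", 0.0)),
                        description=kv.get("desc", ""),
                        removed=kv.get("removed", "false").lower() == "true",
                        regulators=regulators,
                    )
                )
            elif section == "machinery":
                if "=" in line:
                    k, v = line.split("=", 1)
                    mach_params[k.strip()] = float(v)
                else:
                    parts = line.split()
                    if len(parts) != 3:
                        raise ModelSyntaxError(
                            "machinery row needs: mu RNAP ribosome", path, lineno
                        )
                    mach_rows.append(tuple(float(x) for x in parts))
            elif section == "biomass":
                parts = line.split()
                if len(parts) != 2:
                    raise ModelSyntaxError(
                        "biomass row needs: species coefficient", path, lineno
                    )
                defn.biomass.append(
                    PrecursorCoefficient(species=parts[0], coefficient=float(parts[1]))
                )
        except ModelSyntaxError:
            raise
        except (KeyError, ValueError, ConfigurationError) as exc:
            raise ModelSyntaxError(str(exc), path, lineno) from exc
    if mach_rows or mach_params:
        defn.machinery = MachineryProfile(
            table=mach_rows,
            K_rnap=mach_params.get("K_rnap", 0.002),
            K_ribo=mach_params.get("K_ribo", 0.01),
        )
    return defn


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_model(model, path) -> None:
    """Serialise a :class:`ModelDefinition` or network to the model format."""
    if isinstance(model, ReactionNetwork):
        model = model.to_definition()
    out: list[str] = []
    out.append("[species]")
    for sp in model.species:
        out.append(f"{sp.id} {sp.role} {sp.compartment} {_fmt(sp.concentration)}")
    out.append("")
    out.append("[reactions]")
    for rxn in model.reactions:
        subs = " + ".join(
            (f"{_fmt(-c)} {s}" if c != -1 else s)
            for s, c in rxn.stoichiometry.items()
            if c < 0
        )
        prods = " + ".join(
            (f"{_fmt(c)} {s}" if c != 1 else s)
            for s, c in rxn.stoichiometry.items()
            if c > 0
        )
        law = rxn.rate_law
        kv = [f"form={law.form}", f"kcat={_fmt(law.kcat)}"]
        if rxn.catalyst:
            kv.append(f"catalyst={rxn.catalyst}")
        if law.Keq is not None:
            kv.append(f"Keq={_fmt(law.Keq)}")
        kv += [f"Km.{s}={_fmt(v)}" for s, v in law.Km.items()]
        kv += [f"inh.{s}={_fmt(ki)}" for s, ki, _m in law.inhibitors]
        kv += [f"mod.{s}={_fmt(k)}" for s, k in law.modifiers]
        out.append(f"{rxn.id}: {subs} -> {prods} | " + " ".join(kv))
    if model.cycles:
        out.append("")
        out.append("[cycles]")
        for cyc in model.cycles:
            kv = [
                f"target={cyc.target}",
                f"modified={cyc.modified_form}",
                f"converter={cyc.converter}",
                f"k_kin={_fmt(cyc.k_kin)}",
                f"k_phos={_fmt(cyc.k_phos)}",
                f"Km_kin={_fmt(cyc.Km_kin)}",
                f"Km_phos={_fmt(cyc.Km_phos)}",
            ]
            if cyc.kinase_inhibitor is not None:
                kv += [f"inhibitor={cyc.kinase_inhibitor}", f"Ki={_fmt(cyc.Ki_inh)}"]
            out.append(f"{cyc.id}: " + " ".join(kv))
    if model.gene_units:
        out.append("")
        out.append("[genes]")
        for u in model.gene_units:
            kv = [
                f"proteins={','.join(u.member_proteins)}",
                f"promoter={_fmt(u.promoter_conc)}",
                f"copy={_fmt(u.copy_factor)}",
                f"k_tx={_fmt(u.k_tx)}",
                f"mrna_deg={_fmt(u.mRNA_deg)}",
                f"k_tl={_fmt(u.k_tl)}",
                f"protein_deg={_fmt(u.protein_deg)}",
                f"mrna0={_fmt(u.mrna0)}",
            ]
            if u.removed:
                kv.append("removed=true")
            if u.description:
                kv.append(f'desc="{u.description}"')
            for r in u.regulators:
                if r.effector is None:
                    kv.append(f"reg={r.tf}:{r.mode}:{_fmt(r.K_bind)}")
                else:
                    kv.append(
                        f"reg={r.tf}:{r.mode}:{_fmt(r.K_bind)}:"
                        f"{r.effector}:{_fmt(r.K_eff)}:{r.effector_role}"
                    )
            out.append(f"{u.id}: " + " ".join(kv))
    if model.machinery is not None:
        out.append("")
        out.append("[machinery]")
        out.append(f"K_rnap = {_fmt(model.machinery.K_rnap)}")
        out.append(f"K_ribo = {_fmt(model.machinery.K_ribo)}")
        for mu, rnap, ribo in model.machinery.table:
            out.append(f"{_fmt(mu)} {_fmt(rnap)} {_fmt(ribo)}")
    if model.biomass:
        out.append("")
        out.append("[biomass]")
        for entry in model.biomass:
            out.append(f"{entry.species} {_fmt(entry.coefficient)}")
    Path(path).write_text("\n".join(out) + "\n")


def read_growth_profile(path) -> GrowthProfile:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: growth profile needs two columns")
    return GrowthProfile(
        times=df.iloc[:, 0].to_numpy(float), densities=df.iloc[:, 1].to_numpy(float)
    )


def write_growth_profile(profile: GrowthProfile, path) -> None:
    pd.DataFrame({"time_min": profile.times, "X_g_per_L": profile.densities}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def write_timecourse(tc: TimeCourse, path) -> None:
    """TSV with a ``time_min`` column followed by one column per species."""
    df = pd.DataFrame(tc.states.T, columns=tc.species_ids)
    df.insert(0, "time_min", tc.time)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_timecourse(path) -> TimeCourse:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ConfigurationError(f"{path}: cannot parse TSV: {exc}") from exc
    if df.columns[0] != "time_min":
        raise ConfigurationError(f"{path}: first column must be 'time_min'")
    if df.empty:
        return TimeCourse(
            time=np.empty(0),
            states=np.empty((len(df.columns) - 1, 0)),
            fluxes=np.empty((0, 0)),
            species_ids=list(df.columns[1:]),
            reaction_ids=[],
        )
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ConfigurationError(f"{path}: non-numeric value in {col!r} at row {row}")
    species = list(df.columns[1:])
    states = df[species].to_numpy(float).T
    return TimeCourse(
        time=df["time_min"].to_numpy(float),
        states=states,
        fluxes=np.empty((0, len(df))),
        species_ids=species,
        reaction_ids=[],
    )


def model_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
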