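"""Reduced ΔsucA central-metabolism reference model.

A fully parameterised stand-in for the large literature-based model:
PTS glucose uptake (PEP-coupled), glycolysis with explicit PGK / GpmA /
Eno steps, a pentose-phosphate branch producing R5P/X5P/E4P/S7P, the TCA
cycle truncated at α-ketoglutarate by the sucAB knockout, the glyoxylate
shunt under IclR control, the ICD phosphorylation cycle with
3-phosphoglycerate inhibition of the bifunctional kinase/phosphatase, a
glutamate synthesis/export branch, a gene-expression layer for 16
perturbable units, and a biomass composition table that passes the
precursor-table rules.

Parameters are literature-plausible round numbers tuned once so that the
qualitative gene-dosage direction panel holds; they are a stand-in, not a
reproduction of any published parameter set.  Cofactor pools (ATP/ADP,
NAD/NADH, FAD/FADH, CO2, Pi, cAMP) are clamped boundary species, as are
the constitutive enzymes and the Cra/CRP regulator pools.
"""

from __future__ import annotations

import copy

import numpy as np

from .biomass_model import PrecursorCoefficient, apply_side_reactions
from .gene_expression import GeneUnit, MachineryProfile, Regulator, machinery_at
from .model_core import (
    ModelDefinition,
    ModificationCycle,
    RateLaw,
    Reaction,
    ReactionNetwork,
    Species,
    build_network,
)
from .simulation_engine import GrowthProfile, knockout

__all__ = [
    "PERTURBABLE_UNITS",
    "build_reference_model",
    "make_growth_profile",
    "jitter_parameters",
    "expected_sign_panel",
    "classify_direction",
    "match_panel",
    "reference_config",
]

# The curated perturbable roster: the 15 ranked units plus ppc.  The `pdh`
# and `sucAB` units exist in the model (regulation target / knockout
# subject) but are not part of the sweep roster.
PERTURBABLE_UNITS = [
    "icdA",
    "aceBAK",
    "iclR",
    "gdhA",
    "gltA",
    "fba",
    "pdhR",
    "tpiA",
    "ptsG",
    "gpmA",
    "gapA",
    "epd-pgk",
    "crr",
    "pykF",
    "eno",
    "ppc",
]

# observed scale factor > 1 -> amplify-helps; < 1 -> attenuate-helps;
# small finite amplification -> interior-optimum
SIGN_PANEL: dict[str, str] = {
    "icdA": "amplify-helps",
    "aceBAK": "attenuate-helps",
    "iclR": "amplify-helps",
    "gdhA": "amplify-helps",
    "gltA": "amplify-helps",
    "fba": "amplify-helps",
    "pdhR": "interior-optimum",
    "tpiA": "interior-optimum",
    "ptsG": "amplify-helps",
    "gpmA": "attenuate-helps",
    "gapA": "amplify-helps",
    "epd-pgk": "amplify-helps",
    "crr": "amplify-helps",
    "pykF": "interior-optimum",
    "eno": "attenuate-helps",
    "ppc": "amplify-helps",
}

GENE_PRODUCTS = {
    "icdA": "isocitrate dehydrogenase",
    "aceBAK": "malate synthase, isocitrate lyase, ICD kinase/phosphatase",
    "iclR": "isocitrate lyase regulator",
    "gdhA": "glutamate dehydrogenase",
    "gltA": "citrate synthase",
    "fba": "fructose bisphosphate aldolase",
    "pdhR": "pyruvate dehydrogenase complex regulator",
    "tpiA": "triose phosphate isomerase",
    "ptsG": "glucose-specific PTS permease, IICB domain",
    "gpmA": "phosphoglycerate mutase",
    "gapA": "glyceraldehyde-3-phosphate dehydrogenase",
    "epd-pgk": "GAPDH homolog, phosphoglycerate kinase",
    "crr": "glucose-specific PTS permease, IIA domain",
    "pykF": "pyruvate kinase",
    "eno": "enolase",
    "ppc": "PEP carboxylase",
    "pdh": "pyruvate dehydrogenase",
    "sucAB": "alpha-ketoglutarate dehydrogenase",
}


def make_growth_profile(
    t_end: float = 840.0,
    dt: float = 10.0,
    X0: float = 0.5,
    K: float = 8.0,
    r: float = 0.01,
) -> GrowthProfile:
    """Logistic fed-batch-like biomass curve tabulated every ``dt`` minutes.

    mu declines from ~r*(1 - X0/K) toward zero at stationary phase.
    """
    t = np.arange(0.0, t_end + dt / 2, dt)
    X = K * X0 / (X0 + (K - X0) * np.exp(-r * t))
    return GrowthProfile(times=t, densities=X)


def _machinery() -> MachineryProfile:
    return MachineryProfile(
        table=[
            (0.000, 0.0012, 0.006),
            (0.002, 0.0018, 0.009),
            (0.005, 0.0025, 0.015),
            (0.008, 0.0028, 0.018),
            (0.012, 0.0032, 0.022),
            (0.020, 0.0040, 0.030),
        ],
        K_rnap=0.002,
        K_ribo=0.01,
    )


def _biomass_table() -> list[PrecursorCoefficient]:
    """Order-of-magnitude E. coli composition (mmol per g dry weight).

    OAA and FUM are positive (consumed); branch-point key substances (S7P)
    are listed; only even-chain lipid precursor demand enters through
    ACCoA, so no odd-chain species appear.
    """
    rows = [
        ("G6P", 0.12),
        ("F6P", 0.042),
        ("GA3P", 0.08),
        ("3PG", 0.90),
        ("PEP", 0.30),
        ("PYR", 1.70),
        ("ACCoA", 1.80),
        ("OAA", 1.10),
        ("AKG", 0.66),
        ("FUM", 0.18),
        ("R5P", 0.30),
        ("E4P", 0.06),
        ("S7P", 0.006),
    ]
    return [PrecursorCoefficient(species=s, coefficient=c) for s, c in rows]


def _species() -> list[Species]:
    mk = Species
    intra = [
        # glycolysis
        ("G6P", 1.0), ("F6P", 0.25), ("FDP", 1.0), ("DHAP", 0.8), ("GA3P", 0.05),
        ("13DPG", 0.003), ("3PG", 1.5), ("2PG", 0.15), ("PEP", 0.45), ("PYR", 0.8),
        # pentose-phosphate branch
        ("RL5P", 0.15), ("R5P", 0.4), ("X5P", 0.3), ("E4P", 0.3), ("S7P", 0.3),
        # TCA / glyoxylate / glutamate
        ("ACCoA", 0.3), ("OAA", 0.1), ("CIT", 1.0), ("ICIT", 0.065), ("AKG", 0.4),
        ("GLX", 0.02), ("SUC", 0.2), ("FUM", 0.1), ("MAL", 1.0), ("GLU", 2.0),
        ("SUCCoA", 0.05),
        # side-reaction organics
        ("ARG", 0.1), ("AICAR", 0.05), ("GLYCOGEN", 0.1),
    ]
    species = [mk(id=s, role="metabolite", concentration=c) for s, c in intra]
    species += [
        # glucose is clamped: the fed-batch feed keeps the residual pool
        # constant, and consumption is metered through the PTS flux
        mk(id="GLCxt", role="boundary", concentration=180.0, compartment="extracellular"),
        mk(id="GLUxt", role="metabolite", concentration=0.0, compartment="extracellular"),
        mk(id="ACOHxt", role="metabolite", concentration=0.0, compartment="extracellular"),
        # inert counter of cumulative glucose uptake (mM), for the yield basis
        mk(id="GLC_used", role="metabolite", concentration=0.0, compartment="extracellular"),
    ]
    # clamped cofactors and side-reaction feed pools
    boundary = [
        ("CO2", 1.0), ("NAD", 1.0), ("NADH", 0.1), ("FAD", 0.5), ("FADH", 0.05),
        ("ATP", 2.0), ("ADP", 0.5), ("Pi", 10.0), ("cAMP", 0.1),
        ("ARGSUC", 0.1), ("SAICAR", 0.05),
    ]
    species += [mk(id=s, role="boundary", concentration=c) for s, c in boundary]
    # constitutive enzymes (clamped) and constitutive regulators
    const_enzymes = [
        ("PGI_E", 0.01), ("PFK_E", 0.01), ("ZWF_E", 0.01), ("RPI_E", 0.01),
        ("RPE_E", 0.01), ("TKT1_E", 0.01), ("TAL_E", 0.01), ("TKT2_E", 0.01),
        ("ACN_E", 0.01), ("MDH_E", 0.01), ("SDH_E", 0.01), ("FUM_E", 0.01),
        ("SCS_E", 0.01), ("GLUT_E", 0.01),
        ("Cra", 0.001), ("CRP", 0.001),
    ]
    species += [
        mk(id=s, role="boundary", concentration=c, compartment="intracellular")
        for s, c in const_enzymes
    ]
    # proteins of the expression layer (initials set to steady state later)
    proteins = [
        "PTSG", "CRR", "FBA", "TPI", "GAPA", "EPD", "PGK", "GPMA", "ENO",
        "PYKF", "PDH", "PEPC", "CS", "ICD", "ICD-P", "GDH", "ACEA", "ACEB",
        "ICDK", "ICLR", "PDHR", "KGDH",
    ]
    species += [mk(id=p, role="protein", concentration=0.0) for p in proteins]
    return species


def _reactions(p: dict[str, float]) -> list[Reaction]:
    R, L = Reaction, RateLaw

    def irr(kcat, km, inh=None, mods=None):
        return L(
            form="irreversible_mm",
            kcat=kcat,
            Km=dict(km),
            inhibitors=list(inh or []),
            modifiers=list(mods or []),
        )

    def rev(kcat, keq, km):
        return L(form="reversible_mm", kcat=kcat, Keq=keq, Km=dict(km))

    return [
        # glucose uptake: PEP-coupled PTS, IIA (CRR) as saturating modifier
        R(
            id="PTS",
            stoichiometry={"GLCxt": -1, "PEP": -1, "G6P": 1, "PYR": 1, "GLC_used": 1},
            catalyst="PTSG",
            rate_law=irr(
                p["kcat_PTS"],
                {"GLCxt": 5.0, "PEP": 0.02},
                mods=[("CRR", 0.005)],
            ),
        ),
        # upper glycolysis
        R(
            id="PGI",
            stoichiometry={"G6P": -1, "F6P": 1},
            catalyst="PGI_E",
            rate_law=rev(p["kcat_PGI"], 0.3, {"G6P": 1.0, "F6P": 0.5}),
        ),
        R(
            id="PFK",
            stoichiometry={"F6P": -1, "FDP": 1},
            catalyst="PFK_E",
            rate_law=irr(p["kcat_PFK"], {"F6P": 0.3}),
        ),
        R(
            id="FBA",
            stoichiometry={"FDP": -1, "DHAP": 1, "GA3P": 1},
            catalyst="FBA",
            rate_law=rev(p["kcat_FBA"], 0.5, {"FDP": 0.3, "DHAP": 2.0, "GA3P": 2.0}),
        ),
        R(
            id="TPI",
            stoichiometry={"DHAP": -1, "GA3P": 1},
            catalyst="TPI",
            rate_law=rev(p["kcat_TPI"], 0.045, {"DHAP": 1.0, "GA3P": 0.5}),
        ),
        # lower glycolysis: GAPDH moderately limiting, PGK displaced below
        # equilibrium, GpmA partially limiting, Eno of moderate capacity --
        # this is what lets pgk amplification (and gpmA/eno attenuation)
        # raise the 3PG pool
        R(
            id="GAPDH",
            stoichiometry={"GA3P": -1, "13DPG": 1},
            catalyst="GAPA",
            rate_law=rev(p["kcat_GAPDH"], 0.2, {"GA3P": 0.5, "13DPG": 0.1}),
        ),
        R(
            id="PGK",
            stoichiometry={"13DPG": -1, "3PG": 1},
            catalyst="PGK",
            rate_law=rev(p["kcat_PGK"], 1600.0, {"13DPG": 0.002, "3PG": 2.0}),
        ),
        R(
            id="GPM",
            stoichiometry={"3PG": -1, "2PG": 1},
            catalyst="GPMA",
            rate_law=rev(p["kcat_GPM"], 0.19, {"3PG": 15.0, "2PG": 30.0}),
        ),
        R(
            id="ENO",
            stoichiometry={"2PG": -1, "PEP": 1},
            catalyst="ENO",
            rate_law=rev(p["kcat_ENO"], 4.0, {"2PG": 0.5, "PEP": 3.0}),
        ),
        R(
            id="PYK",
            stoichiometry={"PEP": -1, "PYR": 1},
            catalyst="PYKF",
            rate_law=irr(p["kcat_PYK"], {"PEP": 1.0}),
        ),
        # pentose-phosphate branch (lumped oxidative step)
        R(
            id="ZWF",
            stoichiometry={"G6P": -1, "RL5P": 1, "CO2": 1},
            catalyst="ZWF_E",
            rate_law=irr(p["kcat_ZWF"], {"G6P": 1.0}),
        ),
        R(
            id="RPI",
            stoichiometry={"RL5P": -1, "R5P": 1},
            catalyst="RPI_E",
            rate_law=rev(200.0, 3.0, {"RL5P": 0.8, "R5P": 0.8}),
        ),
        R(
            id="RPE",
            stoichiometry={"RL5P": -1, "X5P": 1},
            catalyst="RPE_E",
            rate_law=rev(200.0, 1.5, {"RL5P": 0.8, "X5P": 0.8}),
        ),
        R(
            id="TKT1",
            stoichiometry={"R5P": -1, "X5P": -1, "GA3P": 1, "S7P": 1},
            catalyst="TKT1_E",
            rate_law=rev(150.0, 0.5, {"R5P": 0.5, "X5P": 0.5, "GA3P": 2.0, "S7P": 0.5}),
        ),
        R(
            id="TAL",
            stoichiometry={"GA3P": -1, "S7P": -1, "F6P": 1, "E4P": 1},
            catalyst="TAL_E",
            rate_law=rev(400.0, 1.0, {"GA3P": 0.05, "S7P": 0.5, "F6P": 1.0, "E4P": 0.5}),
        ),
        R(
            id="TKT2",
            stoichiometry={"X5P": -1, "E4P": -1, "F6P": 1, "GA3P": 1},
            catalyst="TKT2_E",
            rate_law=rev(150.0, 10.0, {"X5P": 0.5, "E4P": 0.5, "F6P": 1.0, "GA3P": 2.0}),
        ),
        # pyruvate node and anaplerosis
        R(
            id="PDHr",
            stoichiometry={"PYR": -1, "ACCoA": 1, "CO2": 1},
            catalyst="PDH",
            rate_law=irr(p["kcat_PDH"], {"PYR": 0.5}),
        ),
        # malate feedback on PEP carboxylase: when the lower-TCA pools
        # shrink (e.g. glyoxylate shunt off), PPC disinhibits and keeps the
        # OAA supply for citrate synthase
        R(
            id="PPC",
            stoichiometry={"PEP": -1, "CO2": -1, "OAA": 1},
            catalyst="PEPC",
            rate_law=irr(p["kcat_PPC"], {"PEP": 1.0}, inh=[("MAL", 5.0, "noncompetitive")]),
        ),
        # TCA to AKG, truncated by the sucAB knockout
        R(
            id="CS",
            stoichiometry={"OAA": -1, "ACCoA": -1, "CIT": 1},
            catalyst="CS",
            rate_law=irr(p["kcat_CS"], {"OAA": 0.0005, "ACCoA": 0.5}),
        ),
        R(
            id="ACN",
            stoichiometry={"CIT": -1, "ICIT": 1},
            catalyst="ACN_E",
            rate_law=rev(p["kcat_ACN"], 0.07, {"CIT": 1.0, "ICIT": 0.1}),
        ),
        R(
            id="ICDr",
            stoichiometry={"ICIT": -1, "AKG": 1, "CO2": 1},
            catalyst="ICD",
            rate_law=irr(p["kcat_ICD"], {"ICIT": 0.08}),
        ),
        R(
            id="KGDHr",
            stoichiometry={"AKG": -1, "SUCCoA": 1, "CO2": 1},
            catalyst="KGDH",
            rate_law=irr(p["kcat_KGDH"], {"AKG": 0.3}),
        ),
        R(
            id="SCS",
            stoichiometry={"SUCCoA": -1, "SUC": 1},
            catalyst="SCS_E",
            rate_law=irr(100.0, {"SUCCoA": 0.1}),
        ),
        # glyoxylate shunt
        R(
            id="ICL",
            stoichiometry={"ICIT": -1, "GLX": 1, "SUC": 1},
            catalyst="ACEA",
            rate_law=irr(p["kcat_ICL"], {"ICIT": 0.2}),
        ),
        R(
            id="MS",
            stoichiometry={"GLX": -1, "ACCoA": -1, "MAL": 1},
            catalyst="ACEB",
            rate_law=irr(p["kcat_MS"], {"GLX": 0.05, "ACCoA": 0.1}),
        ),
        # lower TCA back to OAA
        R(
            id="SDH",
            stoichiometry={"SUC": -1, "FUM": 1},
            catalyst="SDH_E",
            rate_law=irr(p["kcat_SDH"], {"SUC": 0.3}),
        ),
        R(
            id="FUMA",
            stoichiometry={"FUM": -1, "MAL": 1},
            catalyst="FUM_E",
            rate_law=rev(100.0, 4.0, {"FUM": 0.3, "MAL": 1.5}),
        ),
        # reversible: the OAA pool (fed by PPC) buffers MAL and, through
        # fumarase, FUM -- the lower-TCA pools survive when shunt flux stops
        R(
            id="MDH",
            stoichiometry={"MAL": -1, "OAA": 1},
            catalyst="MDH_E",
            rate_law=rev(p["kcat_MDH"], 0.01, {"MAL": 1.5, "OAA": 0.05}),
        ),
        # glutamate branch
        R(
            id="GDHr",
            stoichiometry={"AKG": -1, "GLU": 1},
            catalyst="GDH",
            rate_law=rev(p["kcat_GDH"], 30.0, {"AKG": 0.5, "GLU": 20.0}),
        ),
        R(
            id="GLUEX",
            stoichiometry={"GLU": -1, "GLUxt": 1},
            catalyst="GLUT_E",
            rate_law=RateLaw(form="mass_action", kcat=p["k_gluex"]),
        ),
        # acetate overflow valve on acetyl-CoA
        R(
            id="ACEX",
            stoichiometry={"ACCoA": -1, "ACOHxt": 1},
            catalyst=None,
            rate_law=RateLaw(form="mass_action", kcat=p["k_acex"]),
        ),
    ]


# baseline kinetic constants (1/min); tuned once, see scripts/tune_reference.py
DEFAULT_PARAMS: dict[str, float] = {
    "kcat_PTS": 30.0,
    "kcat_PGI": 200.0,
    "kcat_PFK": 60.0,
    "kcat_FBA": 28.0,
    "kcat_TPI": 150.0,
    "kcat_GAPDH": 1070.0,
    "kcat_PGK": 62.0,
    "kcat_GPM": 2300.0,
    "kcat_ENO": 580.0,
    "kcat_PYK": 10.0,
    "kcat_ZWF": 7.0,
    "kcat_PDH": 60.0,
    "kcat_PPC": 60.0,
    "kcat_CS": 45.0,
    "kcat_ACN": 500.0,
    "kcat_ICD": 36.0,
    "kcat_KGDH": 50.0,
    "kcat_ICL": 40.0,
    "kcat_MS": 100.0,
    "kcat_SDH": 20.0,
    "kcat_MDH": 100.0,
    "kcat_GDH": 26.0,
    "k_gluex": 3.0,
    "k_acex": 0.02,
    # ICD phosphorylation cycle
    "k_kin": 2400.0,
    "k_phos": 300.0,
    "Ki_3PG": 0.3,
    "Km_cycle": 10.0,
}

# target baseline protein concentrations (mM) for the expression layer
TARGET_PROTEIN: dict[str, float] = {
    "ptsG": 0.010,
    "crr": 0.005,
    "fba": 0.010,
    "tpiA": 0.010,
    "gapA": 0.010,
    "epd-pgk": 0.010,
    "gpmA": 0.010,
    "eno": 0.010,
    "pykF": 0.010,
    "pdhR": 0.001,
    "ppc": 0.010,
    "gltA": 0.010,
    "icdA": 0.010,
    "gdhA": 0.010,
    "aceBAK": 0.010,
    "iclR": 0.001,
    "pdh": 0.010,
    "sucAB": 0.010,
}

UNIT_PROTEINS: dict[str, list[str]] = {
    "ptsG": ["PTSG"],
    "crr": ["CRR"],
    "fba": ["FBA"],
    "tpiA": ["TPI"],
    "gapA": ["GAPA"],
    "epd-pgk": ["EPD", "PGK"],
    "gpmA": ["GPMA"],
    "eno": ["ENO"],
    "pykF": ["PYKF"],
    "pdhR": ["PDHR"],
    "ppc": ["PEPC"],
    "gltA": ["CS"],
    "icdA": ["ICD"],
    "gdhA": ["GDH"],
    "aceBAK": ["ACEB", "ACEA", "ICDK"],
    "iclR": ["ICLR"],
    "pdh": ["PDH"],
    "sucAB": ["KGDH"],
}


def _regulators(unit_id: str) -> list[Regulator]:
    if unit_id in ("ptsG", "crr"):
        return [
            Regulator(
                tf="CRP", mode="activator", K_bind=3e-4,
                effector="cAMP", K_eff=0.05, effector_role="activates",
            )
        ]
    if unit_id == "aceBAK":
        return [
            Regulator(tf="ICLR", mode="repressor", K_bind=1e-3),
            Regulator(
                tf="Cra", mode="repressor", K_bind=1e-3,
                effector="FDP", K_eff=0.5, effector_role="inactivates",
            ),
        ]
    if unit_id == "pdh":
        return [
            Regulator(
                tf="PDHR", mode="repressor", K_bind=5e-4,
                effector="PYR", K_eff=1.0, effector_role="inactivates",
            )
        ]
    return []


# baseline concentrations used to evaluate regulator occupancy when
# back-computing transcription constants from the protein targets
_BASELINE_FOR_OCC = {
    "CRP": 0.001, "Cra": 0.001, "cAMP": 0.1, "FDP": 1.0, "PYR": 0.3,
    "ICLR": 0.001, "PDHR": 0.001,
}


def _gene_units(machinery: MachineryProfile, mu_ref: float) -> list[GeneUnit]:
    from .gene_expression import regulator_occupancy

    rnap, ribo = machinery_at(machinery, mu_ref)
    sat_rnap = rnap / (machinery.K_rnap + rnap)
    sat_ribo = ribo / (machinery.K_ribo + ribo)
    mdeg, pdeg, ktl = 0.2, 0.008, 1.0
    units = []
    for uid, proteins in UNIT_PROTEINS.items():
        regs = _regulators(uid)
        occ = 1.0
        for reg in regs:
            eff = _BASELINE_FOR_OCC.get(reg.effector) if reg.effector else None
            occ *= regulator_occupancy(reg, _BASELINE_FOR_OCC.get(reg.tf, 0.0), eff)
        p_ss = TARGET_PROTEIN[uid]
        m_ss = p_ss * (pdeg + mu_ref) / (ktl * sat_ribo)
        k_tx = m_ss * (mdeg + mu_ref) / (sat_rnap * occ)
        units.append(
            GeneUnit(
                id=uid,
                member_proteins=list(proteins),
                promoter_conc=1.0,
                copy_factor=1.0,
                k_tx=k_tx,
                mRNA_deg=mdeg,
                k_tl=ktl,
                protein_deg=pdeg,
                regulators=regs,
                mrna0=m_ss,
                description=GENE_PRODUCTS[uid],
            )
        )
    return units


def build_reference_model(
    seed: int | None = None,
    knockout_sucAB: bool = True,
    params: dict[str, float] | None = None,
) -> tuple[ReactionNetwork, GrowthProfile, list[PrecursorCoefficient]]:
    """Build the curated reference model.

    ``seed=None`` returns the fixed curated default; an integer seed applies
    a mild (cv 5%) log-normal jitter to the kinetic constants, deterministic
    per seed.  ``knockout_sucAB`` applies the ΔsucA lesion (default), which
    zeroes all α-ketoglutarate-dehydrogenase flux.
    """
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    profile = make_growth_profile()
    machinery = _machinery()
    mu_ref = profile.mu_at(120.0)
    cycle = ModificationCycle(
        id="icd_cycle",
        target="ICD",
        modified_form="ICD-P",
        converter="ICDK",
        k_kin=p["k_kin"],
        k_phos=p["k_phos"],
        kinase_inhibitor="3PG",
        Ki_inh=p["Ki_3PG"],
        Km_kin=p["Km_cycle"],
        Km_phos=p["Km_cycle"],
    )
    defn = ModelDefinition(
        species=_species(),
        reactions=_reactions(p),
        cycles=[cycle],
        gene_units=_gene_units(machinery, mu_ref),
        machinery=machinery,
        biomass=_biomass_table(),
    )
    # initial protein concentrations at their expression steady state; the
    # ICD pool starts split between active and phosphorylated forms
    by_id = {sp.id: sp for sp in defn.species}
    for uid, proteins in UNIT_PROTEINS.items():
        for pid in proteins:
            by_id[pid].concentration = TARGET_PROTEIN[uid]
    by_id["ICD"].concentration = TARGET_PROTEIN["icdA"] * 0.5
    by_id["ICD-P"].concentration = TARGET_PROTEIN["icdA"] * 0.5
    network = build_network(defn)
    network = apply_side_reactions(
        network, rate_constants={"eqA": 1e-3, "eqB": 1e-3, "glycogen": 1e-4}
    )
    if knockout_sucAB:
        network = knockout(network, "sucAB")
    if seed is not None:
        network = jitter_parameters(network, cv=0.05, seed=seed)
    return network, profile, _biomass_table()


def reference_config(**overrides) -> "SimulationConfig":
    """Simulation settings used for reference-model runs and sweeps.

    Slightly looser tolerances than the engine default keep a 61-point,
    16-unit sweep tractable on one CPU; consumption is metered through the
    clamped-glucose PTS uptake flux.
    """
    from .simulation_engine import SimulationConfig

    kwargs = dict(rel_tol=1e-6, abs_tol=1e-9, consumption_species="GLC_used")
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def jitter_parameters(
    network: ReactionNetwork, cv: float, seed: int | None = None
) -> ReactionNetwork:
    """Multiply every kinetic constant by an independent log-normal factor.

    ``cv`` is the relative spread (0 < cv < 1); structure, expression
    constants and initial concentrations are unchanged.
    """
    if not (0 < cv < 1):
        raise ValueError(f"cv must be in (0, 1), got {cv}")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv * cv)))

    def factor() -> float:
        return float(rng.lognormal(mean=0.0, sigma=sigma))

    net = copy.deepcopy(network)
    for rxn in net.reactions:
        law = rxn.rate_law
        law.kcat *= factor()
        law.Km = {s: km * factor() for s, km in law.Km.items()}
        if law.Keq is not None:
            law.Keq *= factor()
        law.inhibitors = [(s, ki * factor(), m) for s, ki, m in law.inhibitors]
        law.modifiers = [(s, k * factor()) for s, k in law.modifiers]
        rxn.bind()
    for cyc in net.cycles:
        cyc.k_kin *= factor()
        cyc.k_phos *= factor()
        cyc.Km_kin *= factor()
        cyc.Km_phos *= factor()
        if cyc.Ki_inh is not None:
            cyc.Ki_inh *= factor()
    return net


def expected_sign_panel() -> dict[str, str]:
    """Curated expected dosage direction for each perturbable unit."""
    return dict(SIGN_PANEL)


def classify_direction(
    scale_factor: float,
    max_sensitivity: float,
    interior_max: float = 30.0,
    flat_tol: float = 1e-4,
) -> str:
    """Map a sweep summary onto a direction label.

    < 1 -> attenuate-helps; within (1, interior_max] -> interior-optimum;
    above -> amplify-helps; an essentially flat curve -> "flat".
    """
    if max_sensitivity <= flat_tol:
        return "flat"
    if scale_factor < 1.0:
        return "attenuate-helps"
    if scale_factor <= interior_max:
        return "interior-optimum"
    return "amplify-helps"


def match_panel(
    results: dict, panel: dict[str, str] | None = None, interior_max: float = 30.0
) -> dict[str, bool]:
    """Per-unit agreement of sweep results with the expected sign panel.

    ``amplify-helps`` is satisfied by any observed optimum above 1
    (including an interior one); ``interior-optimum`` requires the optimum
    in (1, interior_max]; ``attenuate-helps`` requires it below 1.
    """
    panel = panel or expected_sign_panel()
    agree: dict[str, bool] = {}
    for uid, expected in panel.items():
        if uid not in results:
            agree[uid] = False
            continue
        res = results[uid]
        obs = classify_direction(res.scale_factor, res.max_sensitivity, interior_max)
        if expected == "amplify-helps":
            agree[uid] = obs in ("amplify-helps", "interior-optimum")
        else:
            agree[uid] = obs == expected
    return agree
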