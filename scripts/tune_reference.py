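"""Diagnostic/tuning harness for the reference model.

Prints the baseline trajectory summary, flux snapshot, ICD phosphorylation
state, and quick coarse sweeps for selected gene units.  The final tuned
constants live in ``glusim.reference_model.DEFAULT_PARAMS``.

Usage: python scripts/tune_reference.py [unit ...]
"""

import sys
import time

import numpy as np

from glusim import build_reference_model, simulate, yield_metric
from glusim.reference_model import PERTURBABLE_UNITS, reference_config
from glusim.sensitivity import PerturbationGrid, sweep_gene
from glusim.simulation_engine import assemble_odes


def baseline_report():
    net, prof, bm = build_reference_model()
    cfg = reference_config()
    t0 = time.time()
    tc = simulate(net, prof, cfg)
    y0 = yield_metric(tc)
    print(f"baseline: {time.time() - t0:.2f}s  Y0={y0:.4f}")
    consumed = np.trapezoid(tc.flux_series("PTS"), tc.time)
    print(f"glucose consumed {consumed:.1f} mM, GLUxt {tc.final('GLUxt'):.1f}, "
          f"ACOHxt {tc.final('ACOHxt'):.1f}")
    watch = ["G6P", "F6P", "FDP", "GA3P", "3PG", "2PG", "PEP", "PYR", "ACCoA",
             "OAA", "CIT", "ICIT", "AKG", "GLU", "S7P", "R5P", "E4P", "MAL"]
    for sid in watch:
        s = tc.series(sid)
        print(f"  {sid:>6} end={s[-1]:9.4f} min={s.min():9.4f} max={s.max():9.4f}")
    icd, icdp = tc.series("ICD"), tc.series("ICD-P")
    frac = icdp / (icd + icdp)
    print(f"  ICD-P fraction: {frac.min():.3f} .. {frac.max():.3f}")
    mid = tc.time.size // 3
    print("  fluxes at t=%g:" % tc.time[mid])
    for rid in tc.reaction_ids:
        print(f"    {rid:>10} {tc.flux_series(rid)[mid]:9.4f}")
    return net, prof, cfg, y0


def mini_sweep(net, prof, cfg, y0, units):
    grid = PerturbationGrid(
        np.array([0.001, 0.01, 0.1, 0.3, 1.0, 1.5, 3.0, 5.0, 10.0, 100.0, 1000.0])
    )
    for uid in units:
        t0 = time.time()
        res = sweep_gene(net, prof, cfg, uid, grid, baseline=y0)
        pts = "  ".join(f"{f:g}:{(y - y0) / y0:+.3f}" for f, y in res.curve)
        print(f"{uid:>8} ({time.time() - t0:.1f}s) best {res.max_sensitivity:+.4f} "
              f"@ {res.scale_factor:g}   [{pts}]  failed={res.failed_factors}")


if __name__ == "__main__":
    net, prof, cfg, y0 = baseline_report()
    units = sys.argv[1:] or PERTURBABLE_UNITS
    mini_sweep(net, prof, cfg, y0, units)
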