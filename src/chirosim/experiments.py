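"""Named scenario presets and parameter-sweep drivers.

Each scenario reproduces one of the study's printed configurations:

* ``fig2a_*`` — template-directed symmetry breaking after inoculating 50
  homochiral D 6-mers (P_TL = 0.01, P_RL = 0), with complete / partial / no
  chiral selection and a no-termination control;
* ``fig2b`` — de novo appearance of RNA (P_RL = 1e-6, F_CST = 0.5,
  F_CSS = 0);
* ``fig3_*`` — surface-mediated synthesis alone (P_AT = 0, P_NDE = 1e-5,
  F_CSS = 0) under primer-effect ladders of increasing strength;
* ``fig4a_nsr`` / ``fig4b_rep`` — spontaneous ribozyme emergence on a
  chirality-deviation background (moderate ladders, one catalytic rate on).

Full-scale presets use the printed grid (N = 20, T_NPB = 50000) and run for
millions of steps; every scenario also has a ``_reduced`` variant (N = 10,
T_NPB = 2000, 2e5 steps, inoculation at 5e4) that keeps all probabilities
and ladders unchanged and completes in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import D, Params, PrimerLadder
from .engine import InoculationEvent, RunConfig, run

__all__ = ["Scenario", "scenario", "scenario_names", "sweep",
           "REDUCED_N", "REDUCED_T_NPB", "REDUCED_STEPS"]

# Primer-effect ladders as printed (R1 normalised to 1; Rn = R3 throughout)
LADDER_UNIFORM = PrimerLadder(1, 1, 1, 1)
LADDER_50 = PrimerLadder(1, 10, 50, 50)     # Rn = R3 = 5 x R2 = 50 x R1
LADDER_100 = PrimerLadder(1, 10, 100, 100)  # Rn = R3 = 10 x R2 = 100 x R1
LADDER_200 = PrimerLadder(1, 10, 200, 200)  # Rn = R3 = 20 x R2 = 200 x R1
LADDER_SURF_20 = PrimerLadder(1, 10, 20, 20)   # Rn = R3 = 2 x R2 = 20 x R1
LADDER_TMPL_10 = PrimerLadder(1, 5, 10, 10)    # Rn = R3 = 2 x R2 = 10 x R1

REDUCED_N = 10
REDUCED_T_NPB = 2000
REDUCED_STEPS = 200_000
REDUCED_INOC_STEP = 50_000
FULL_INOC_STEP = 1_000_000


@dataclass(frozen=True)
class Scenario:
    name: str
    config: RunConfig
    expected_regime: str  # no_deviation | deviation | deviation_then_ribozyme


def _fig2a(f_cst: float, no_termination: bool = False):
    params = Params(P_TL=0.01, P_RL=0.0, F_CST=f_cst)
    inoc = InoculationEvent(step=FULL_INOC_STEP, count=50, length=6, chirality=D)
    return params, (inoc,), no_termination


_SCENARIOS = {}


def _register(name, params, steps, regime, inoculations=(), no_termination=False):
    _SCENARIOS[name] = (params, steps, regime, inoculations, no_termination)


_p, _i, _ = _fig2a(0.0)
_register("fig2a_complete", _p, 3_000_000, "deviation", _i)
_p, _i, _ = _fig2a(0.5)
_register("fig2a_partial", _p, 3_000_000, "deviation", _i)
_p, _i, _ = _fig2a(1.0)
_register("fig2a_noselect", _p, 3_000_000, "deviation", _i)
_p, _i, _ = _fig2a(1.0, True)
_register("fig2a_notermination", _p, 3_000_000, "no_deviation", _i,
          no_termination=True)
_register("fig2b",
          Params(P_TL=0.01, P_RL=1e-6, F_CST=0.5, F_CSS=0.0),
          3_000_000, "deviation")
for _nm, _lad, _reg in (
    ("fig3_uniform", LADDER_UNIFORM, "no_deviation"),
    ("fig3_ladder50", LADDER_50, "no_deviation"),
    ("fig3_ladder100", LADDER_100, "deviation"),
    ("fig3_ladder200", LADDER_200, "deviation"),
):
    _register(_nm,
              Params(P_AT=0.0, P_RL=1e-6, P_NDE=1e-5, F_CSS=0.0,
                     R_surface=_lad),
              3_000_000, _reg)
_register("fig4a_nsr",
          Params(P_NFR=0.2, P_TLR=0.0,
                 R_surface=LADDER_SURF_20, R_template=LADDER_TMPL_10),
          6_000_000, "deviation_then_ribozyme")
_register("fig4b_rep",
          Params(P_NFR=0.0, P_TLR=0.9,
                 R_surface=LADDER_SURF_20, R_template=LADDER_TMPL_10),
          6_000_000, "deviation_then_ribozyme")


def scenario_names(include_reduced: bool = True) -> list[str]:
    names = sorted(_SCENARIOS)
    if include_reduced:
        names += [n + "_reduced" for n in sorted(_SCENARIOS)]
    return names


def scenario(name: str, seed: int = 0) -> Scenario:
    """Look up a named preset (append ``_reduced`` for the desk-scale
    variant); raises KeyError for unknown names."""
    reduced = name.endswith("_reduced")
    base = name[:-len("_reduced")] if reduced else name
    if base not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; "
                       f"known: {', '.join(scenario_names(False))}")
    params, steps, regime, inoculations, no_termination = _SCENARIOS[base]
    if reduced:
        params = params.replace(N=REDUCED_N, T_NPB=REDUCED_T_NPB)
        steps = REDUCED_STEPS
        inoculations = tuple(
            ev if ev.step < steps else
            InoculationEvent(step=REDUCED_INOC_STEP, count=ev.count,
                             length=ev.length, chirality=ev.chirality,
                             sequence=ev.sequence)
            for ev in inoculations)
    config = RunConfig(params=params, steps=steps, seed=seed,
                       inoculations=inoculations,
                       no_termination=no_termination,
                       record_every=1000)
    return Scenario(name=name, config=config, expected_regime=regime)


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """Distinct, recorded child seeds derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def sweep(base_scenario, parameter: str, values, replicates: int = 1,
          seed: int = 0) -> pd.DataFrame:
    """Run a one-parameter grid and tabulate the resulting ee.

    ``base_scenario`` is a Scenario or scenario name; ``parameter`` names a
    Params field.  Returns one row per (value, replicate) with the final ee,
    the time-averaged ee over the final half of the run, and their absolute
    values (the study reports |ee| where the prevailing handedness is
    arbitrary).
    """
    if isinstance(base_scenario, str):
        base_scenario = scenario(base_scenario)
    seeds = replicate_seeds(seed, replicates * len(list(values)))
    rows = []
    idx = 0
    for value in values:
        params = base_scenario.config.params.replace(**{parameter: value})
        for rep in range(replicates):
            config = base_scenario.config.replace(params=params, seed=seeds[idx])
            idx += 1
            traj = run(config)
            final = traj.final_ee
            mean_half = traj.mean_ee_last_half()
            rows.append({
                "parameter": parameter, "value": value, "replicate": rep,
                "seed": config.seed, "final_ee": final,
                "mean_ee_last_half": mean_half,
                "abs_final_ee": abs(final),
                "abs_mean_ee_last_half": abs(mean_half),
            })
    return pd.DataFrame(rows)
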