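"""Plain-text run configuration (KEY=VALUE).

Parameter keys follow the standard symbols (P_AT, F_CST, CS_NSR, ...).
Primer ladders are comma lists ``R_SURFACE=R1,R2,R3,Rn``; run-level keys are
STEPS, SEED, RECORD_EVERY, NO_TERMINATION and repeatable
``INOCULATE=step:count:length:chirality:sequence`` lines.
"""

from __future__ import annotations

import dataclasses

from .core import Chirality, Params, PrimerLadder
from .engine import InoculationEvent, RunConfig

__all__ = ["read_config", "write_config", "parse_config"]

_FLOAT_KEYS = {
    "P_AT", "P_BB", "P_CIC", "P_FP", "P_MN", "P_MPN", "P_ND", "P_NDE",
    "P_NF", "P_NFR", "P_RL", "P_SP", "P_TL", "P_TLR", "F_CSS", "F_CST",
}
_INT_KEYS = {"N", "T_NPB", "C_T"}
_STR_KEYS = {"CS_REP", "CS_NSR", "NEIGHBORHOOD"}


class ConfigError(ValueError):
    pass


def parse_config(text: str) -> RunConfig:
    params_kw = {}
    run_kw = {"steps": 0}
    inoculations = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected KEY=VALUE, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        key = key.upper()
        try:
            if key in _FLOAT_KEYS:
                params_kw[key] = float(value)
            elif key in _INT_KEYS:
                params_kw[key] = int(value)
            elif key in _STR_KEYS:
                field = "neighborhood" if key == "NEIGHBORHOOD" else key
                params_kw[field] = value
            elif key in ("R_SURFACE", "R_TEMPLATE"):
                parts = [float(v) for v in value.split(",")]
                if len(parts) != 4:
                    raise ValueError("ladder needs four multipliers R1,R2,R3,Rn")
                field = "R_surface" if key == "R_SURFACE" else "R_template"
                params_kw[field] = PrimerLadder(*parts)
            elif key == "STEPS":
                run_kw["steps"] = int(float(value))
            elif key == "SEED":
                run_kw["seed"] = int(value)
            elif key == "RECORD_EVERY":
                run_kw["record_every"] = int(float(value))
            elif key == "NO_TERMINATION":
                run_kw["no_termination"] = value.strip() in ("1", "true", "True", "yes")
            elif key == "INOCULATE":
                parts = value.split(":")
                if len(parts) not in (4, 5):
                    raise ValueError(
                        "expected step:count:length:chirality[:sequence]")
                step, count, length = (int(float(v)) for v in parts[:3])
                chirality = Chirality[parts[3].strip().upper()]
                sequence = parts[4].strip() if len(parts) == 5 else "random"
                inoculations.append(InoculationEvent(
                    step=step, count=count, length=length,
                    chirality=chirality, sequence=sequence))
            else:
                raise ValueError(f"unknown key {key}")
        except (ValueError, KeyError) as exc:
            raise ConfigError(f"line {lineno}: {exc}") from None
    try:
        params = Params(**params_kw)
        return RunConfig(params=params, inoculations=tuple(inoculations), **run_kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from None


def read_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config(fh.read())


def write_config(config: RunConfig, path) -> None:
    p = config.params
    lines = []
    for f in dataclasses.fields(Params):
        v = getattr(p, f.name)
        if f.name in ("R_surface", "R_template"):
            key = f.name.upper()
            lines.append(f"{key}={','.join(repr(x) for x in v.as_tuple())}")
        elif f.name == "neighborhood":
            lines.append(f"NEIGHBORHOOD={v}")
        else:
            lines.append(f"{f.name}={v!r}" if isinstance(v, float) else f"{f.name}={v}")
    lines.append(f"STEPS={config.steps}")
    lines.append(f"SEED={config.seed}")
    lines.append(f"RECORD_EVERY={config.record_every}")
    lines.append(f"NO_TERMINATION={int(config.no_termination)}")
    for ev in config.inoculations:
        lines.append(
            f"INOCULATE={ev.step}:{ev.count}:{ev.length}:"
            f"{ev.chirality.name}:{ev.sequence}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
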