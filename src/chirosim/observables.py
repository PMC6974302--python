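"""Trajectory statistics and serialisation.

The observables follow the study's figures: the enantiomeric excess
ee = (D - L)/(D + L) over all chiral material, per-handedness totals,
chain-length distributions (capped at 20 residues with an overflow bin,
matching the figures' display cap) and active ribozyme counts.  Chains
inside template complexes are counted, template and attachments each as a
chain of its own length; free nucleotides appear as 1-mers (their canonical
chain representation); precursors are not chains.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BASES, D, detect_ribozyme
from .state import SystemState, ee_statistic

__all__ = [
    "LENGTH_CAP",
    "TrajectoryRecord",
    "Trajectory",
    "record",
    "write_trajectory",
    "read_trajectory",
    "snapshot",
]

LENGTH_CAP = 20


@dataclass(frozen=True)
class TrajectoryRecord:
    """One sampled time point; a pure function of the state."""

    step: int
    ee: float
    D_total: int
    L_total: int
    nsr_D: int
    nsr_L: int
    rep_D: int
    rep_L: int
    length_hist_D: tuple  # chain counts for lengths 1..20, then >20
    length_hist_L: tuple


def _chain_slot_class(chirs: np.ndarray) -> int:
    """Histogram class of a chain: majority handedness slot, ties resolved
    by the first residue (a slot-based rule, so mirror-consistent)."""
    ones = int(np.count_nonzero(chirs))
    m = len(chirs)
    if ones * 2 > m:
        return 1
    if ones * 2 < m:
        return 0
    return int(chirs[0])


def record(state: SystemState) -> TrajectoryRecord:
    p = state.params
    hist = np.zeros((2, LENGTH_CAP + 1), dtype=np.int64)
    riboz = np.zeros((2, 2), dtype=np.int64)  # [nsr|rep, slot]
    nuc2 = state.nuc.reshape(state.R, 2, 4)
    hist[0, 0] += int(nuc2[:, 0, :].sum())
    hist[1, 0] += int(nuc2[:, 1, :].sum())
    for slot in np.flatnonzero(state.ch_len):
        slot = int(slot)
        m = int(state.ch_len[slot])
        chirs = state.ch_chir[slot, :m]
        hist[_chain_slot_class(chirs), min(m, LENGTH_CAP + 1) - 1] += 1
        if state.ch_free[slot]:
            chain = state.chain_object(slot)
            for row, domain in ((0, p.CS_NSR), (1, p.CS_REP)):
                active, chir = detect_ribozyme(chain, domain)
                if active:
                    # engine chain bytes hold slot values, so int(chir) is
                    # the internal slot of the catalytic core
                    riboz[row, int(chir)] += 1
    d, l = state.enantiomer_totals()
    sd = 0 if state.labels[0] is D else 1
    sl = 1 - sd
    return TrajectoryRecord(
        step=state.step,
        ee=ee_statistic(state),
        D_total=d,
        L_total=l,
        nsr_D=int(riboz[0, sd]), nsr_L=int(riboz[0, sl]),
        rep_D=int(riboz[1, sd]), rep_L=int(riboz[1, sl]),
        length_hist_D=tuple(int(v) for v in hist[sd]),
        length_hist_L=tuple(int(v) for v in hist[sl]),
    )


@dataclass
class Trajectory:
    """The recorded time series of one run."""

    records: list
    config: object = None
    final_state: object = None

    def steps(self) -> np.ndarray:
        return np.array([r.step for r in self.records])

    def ee_series(self) -> np.ndarray:
        return np.array([r.ee for r in self.records])

    @property
    def final_ee(self) -> float:
        return self.records[-1].ee

    def mean_ee_last_half(self) -> float:
        """Time-averaged ee over the final half of the recorded run."""
        ee = self.ee_series()
        return float(ee[len(ee) // 2:].mean())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "step": r.step, "ee": r.ee,
                "D_total": r.D_total, "L_total": r.L_total,
                "nsr_D": r.nsr_D, "nsr_L": r.nsr_L,
                "rep_D": r.rep_D, "rep_L": r.rep_L,
            }
            for label, hist in (("D", r.length_hist_D), ("L", r.length_hist_L)):
                for i in range(LENGTH_CAP):
                    row[f"len_{i + 1}_{label}"] = hist[i]
                row[f"len_gt{LENGTH_CAP}_{label}"] = hist[LENGTH_CAP]
            rows.append(row)
        return pd.DataFrame(rows)


def _config_hash(config) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def write_trajectory(trajectory, path) -> None:
    """Write a trajectory (or a bare record list) as headered TSV."""
    if isinstance(trajectory, Trajectory):
        records, config = trajectory.records, trajectory.config
    else:
        records, config = list(trajectory), None
    frame = Trajectory(records=list(records)).to_frame()
    seed = getattr(config, "seed", "NA") if config is not None else "NA"
    with open(path, "w") as fh:
        fh.write("# chirosim trajectory v1\n")
        fh.write(f"# seed={seed}\n")
        fh.write(f"# config={_config_hash(config) if config is not None else 'NA'}\n")
        if not frame.empty:
            frame.to_csv(fh, sep="\t", index=False)


def read_trajectory(path):
    """Read a trajectory TSV back into (records, metadata).

    Raises ValueError naming the offending line on malformed input.
    """
    meta = {}
    body = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            text = line[1:].strip()
            if "=" in text:
                k, v = text.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if line.strip():
            body.append((lineno, line))
    if not body:
        return [], meta
    ncols = len(body[0][1].rstrip("\n").split("\t"))
    for lineno, line in body[1:]:
        if len(line.rstrip("\n").split("\t")) != ncols:
            raise ValueError(f"malformed trajectory file {path}: line {lineno}")
    frame = pd.read_csv(io.StringIO("".join(l for _, l in body)), sep="\t",
                        float_precision="round_trip")
    records = []
    for _, row in frame.iterrows():
        records.append(TrajectoryRecord(
            step=int(row["step"]), ee=float(row["ee"]),
            D_total=int(row["D_total"]), L_total=int(row["L_total"]),
            nsr_D=int(row["nsr_D"]), nsr_L=int(row["nsr_L"]),
            rep_D=int(row["rep_D"]), rep_L=int(row["rep_L"]),
            length_hist_D=tuple(
                int(row[f"len_{i + 1}_D"]) for i in range(LENGTH_CAP)
            ) + (int(row[f"len_gt{LENGTH_CAP}_D"]),),
            length_hist_L=tuple(
                int(row[f"len_{i + 1}_L"]) for i in range(LENGTH_CAP)
            ) + (int(row[f"len_gt{LENGTH_CAP}_L"]),),
        ))
    return records, meta


def snapshot(state: SystemState, path) -> None:
    """Per-molecule TSV snapshot (room coordinates, species, handedness,
    length, sequence, ribozyme flag): the data behind the study's spatial
    frames; rendering is left to external tools."""
    p = state.params
    N = state.N
    label_of = [state.label(0).name, state.label(1).name]
    with open(path, "w") as fh:
        fh.write("row\tcol\tspecies\tchirality\tlength\tsequence\tribozyme\n")
        for r in range(state.R):
            i, j = divmod(r, N)
            for s in (0, 1):
                for _ in range(int(state.prec[r, s])):
                    fh.write(f"{i}\t{j}\tprecursor\t{label_of[s]}\t1\t.\t-\n")
                for b in range(4):
                    for _ in range(int(state.nuc[r, s * 4 + b])):
                        fh.write(f"{i}\t{j}\tnucleotide\t{label_of[s]}\t1\t{BASES[b]}\t-\n")
        for slot in np.flatnonzero(state.ch_free):
            slot = int(slot)
            chain = state.chain_object(slot)
            r = int(state.ch_room[slot])
            i, j = divmod(r, N)
            flags = []
            for name, domain in (("NSR", p.CS_NSR), ("REP", p.CS_REP)):
                if detect_ribozyme(chain, domain)[0]:
                    flags.append(name)
            chir = label_of[_chain_slot_class(state.ch_chir[slot, :len(chain)])]
            if not chain.is_homochiral():
                chir = "mixed"
            fh.write(f"{i}\t{j}\tchain\t{chir}\t{len(chain)}\t"
                     f"{chain.sequence()}\t{','.join(flags) or '-'}\n")
        for x in state.complex_slots():
            x = int(x)
            r = int(state.cx_room[x])
            i, j = divmod(r, N)
            t = int(state.cx_tmpl[x])
            tmpl = state.chain_object(t)
            mass = state.complex_mass(x)
            chir = label_of[_chain_slot_class(state.ch_chir[t, :len(tmpl)])]
            if not tmpl.is_homochiral():
                chir = "mixed"
            fh.write(f"{i}\t{j}\tcomplex\t{chir}\t{mass}\t{tmpl.sequence()}\t-\n")
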