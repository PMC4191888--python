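"""Plain-text persistence: conformation snapshots, run directories, XYZ.

Snapshot format (one file per conformation)::

    # N L mcs_clock
    0 x y z
    1 x y z
    ...
    i j expires_at     <- one line per active loop bond

The first N body lines are monomers ("index x y z"), any further lines are
loop bonds.  Everything is integer, whitespace-separated; lines starting
with '#' outside the header are ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import Conformation
from .loops import DomainLayout

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_xyz",
    "write_rg2_table",
    "read_rg2_table",
    "write_event_log",
    "read_event_log",
]

EVENT_COLUMNS = ["mcs", "event", "i", "j", "lifetime"]


def write_snapshot(conf: Conformation, path) -> None:
    lines = [f"# {conf.N} {conf.L} {conf.mcs_clock}"]
    for m, (x, y, z) in enumerate(conf.positions):
        lines.append(f"{m} {x} {y} {z}")
    for (i, j), exp in sorted(conf.loop_bonds.items()):
        lines.append(f"{i} {j} {exp}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path) -> Conformation:
    raw = Path(path).read_text().splitlines()
    if not raw or not raw[0].startswith("#"):
        raise ValueError(f"{path}: missing '# N L mcs_clock' header")
    N, L, clock = (int(tok) for tok in raw[0][1:].split())
    body = [ln for ln in raw[1:] if ln.strip() and not ln.startswith("#")]
    if len(body) < N:
        raise ValueError(f"{path}: expected {N} monomer lines, found {len(body)}")
    positions = np.empty((N, 3), dtype=np.int64)
    for ln in body[:N]:
        idx, x, y, z = (int(tok) for tok in ln.split())
        positions[idx] = (x, y, z)
    loop_bonds = {}
    for ln in body[N:]:
        i, j, exp = (int(tok) for tok in ln.split())
        loop_bonds[(min(i, j), max(i, j))] = exp
    return Conformation(positions=positions, L=L, mcs_clock=clock,
                        loop_bonds=loop_bonds)


def write_xyz(conf: Conformation, path, layout: DomainLayout | None = None) -> None:
    """XYZ export of unwrapped coordinates for visualization; the element
    tag distinguishes looped-domain (C) from linker (N) monomers when a
    layout is given."""
    pos = conf.unwrapped_positions()
    lines = [str(conf.N), f"mcs={conf.mcs_clock}"]
    for m, (x, y, z) in enumerate(pos):
        tag = "C"
        if layout is not None and layout.is_linker[m]:
            tag = "N"
        lines.append(f"{tag} {x} {y} {z}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_rg2_table(mcs_times, rg2, path) -> None:
    pd.DataFrame({"mcs": mcs_times, "rg2": rg2}).to_csv(path, sep="\t", index=False)


def read_rg2_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_event_log(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_event_log(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
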