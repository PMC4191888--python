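"""FISH-style locus geometry: probe-pair distance tables and radial
nuclear positions.

The experimental counterpart of the simulated MSD curve is a table of 3D
distances R (um) between pairs of FISH probes at known genomic separation
g (Mb), aggregated per g into <R^2>.  Radial position of a labelled locus
is expressed as p_n = r_o / r_n: the distance of the probe from the
nuclear centre of gravity divided by the length of the line from the
centre through the probe to the nuclear envelope (0 = centre,
1 = periphery).

Tables are TSV with fixed headers (units in the column names):

probe pairs:  pair_id  genomic_distance_mb  distance_um  experiment
radial:       probe_id  r_o_um  r_n_um
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .observables import msd_profile
from .protocol import EnsembleRecord

__all__ = [
    "PAIR_COLUMNS",
    "RADIAL_COLUMNS",
    "read_pair_table",
    "write_pair_table",
    "read_radial_table",
    "write_radial_table",
    "msd_vs_genomic",
    "radial_position",
    "synthesize_fish_table",
]

PAIR_COLUMNS = ["pair_id", "genomic_distance_mb", "distance_um", "experiment"]
RADIAL_COLUMNS = ["probe_id", "r_o_um", "r_n_um"]


def _require_columns(df: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PAIR_COLUMNS[:3])
    if "experiment" not in df.columns:
        df["experiment"] = "exp1"
    return df


def write_pair_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, PAIR_COLUMNS[:3])
    df.to_csv(path, sep="\t", index=False)


def read_radial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, RADIAL_COLUMNS)
    return df


def write_radial_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, RADIAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def msd_vs_genomic(records: pd.DataFrame) -> pd.DataFrame:
    """<R^2> per unique genomic distance g.

    Returns a frame with columns (genomic_distance_mb, msd_um2, sem_um2,
    n, n_experiments).  SEM is over all measurements at that g;
    per-experiment counts are retained via n_experiments so the design
    range (tens to low hundreds of measurements per point) can be checked.
    Genomic distances with fewer than 2 measurements are dropped with a
    warning.
    """
    _require_columns(records, PAIR_COLUMNS[:3])
    if len(records) == 0:
        raise ValueError("empty probe-pair table")
    if (records["genomic_distance_mb"] <= 0).any():
        raise ValueError("genomic distances must be positive")
    if (records["distance_um"] < 0).any():
        raise ValueError("3D distances must be non-negative")

    exp = records["experiment"] if "experiment" in records.columns else "exp1"
    df = records.assign(_r2=records["distance_um"] ** 2, _exp=exp)
    rows = []
    for g, grp in df.groupby("genomic_distance_mb", sort=True):
        if len(grp) < 2:
            warnings.warn(
                f"genomic distance g={g} has a single measurement; excluded",
                stacklevel=2,
            )
            continue
        r2 = grp["_r2"].to_numpy()
        rows.append(
            {
                "genomic_distance_mb": g,
                "msd_um2": r2.mean(),
                "sem_um2": r2.std(ddof=1) / np.sqrt(len(r2)),
                "n": len(r2),
                "n_experiments": grp["_exp"].nunique(),
            }
        )
    if not rows:
        raise ValueError("no genomic distance has >= 2 measurements")
    return pd.DataFrame(rows)


def radial_position(r_o, r_n):
    """Normalized radial nuclear position p_n = r_o / r_n in [0, 1]."""
    r_o = np.asarray(r_o, dtype=float)
    r_n = np.asarray(r_n, dtype=float)
    if (r_n <= 0).any():
        raise ValueError("r_n must be positive")
    if (r_o < 0).any() or (r_o > r_n).any():
        raise ValueError("require 0 <= r_o <= r_n")
    p = r_o / r_n
    return float(p) if p.ndim == 0 else p


def synthesize_fish_table(ensemble: EnsembleRecord, *, scale: float,
                          mb_per_monomer: float, noise_sd: float,
                          probe_positions, seed: int) -> pd.DataFrame:
    """Emulate a FISH probe-pair table from a simulated ensemble.

    Probes sit on monomers; for every conformation and probe pair the
    genomic separation is |i - j| * mb_per_monomer (Mb) and the measured
    distance is |scale * (x_j - x_i) + eps| with isotropic 3D Gaussian
    localisation noise eps of per-axis standard deviation ``noise_sd`` um
    (so E[R^2] picks up an additive 3*noise_sd^2 term).  Each conformation
    is labelled as one "experiment".
    """
    if scale <= 0 or mb_per_monomer <= 0:
        raise ValueError("scale and mb_per_monomer must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    probes = np.asarray(probe_positions, dtype=np.int64)
    N = ensemble.N
    if probes.min() < 0 or probes.max() >= N:
        raise ValueError(f"probe positions must lie in [0, {N})")

    rng = np.random.default_rng(seed)
    rows = []
    for ci, conf in enumerate(ensemble.conformations):
        pos = conf.unwrapped_positions().astype(np.float64)
        for a in range(len(probes)):
            for b in range(a + 1, len(probes)):
                i, j = int(probes[a]), int(probes[b])
                if i == j:
                    continue
                vec = scale * (pos[j] - pos[i])
                if noise_sd > 0:
                    vec = vec + rng.normal(0.0, noise_sd, size=3)
                rows.append(
                    {
                        "pair_id": f"m{min(i, j)}-m{max(i, j)}",
                        "genomic_distance_mb": abs(j - i) * mb_per_monomer,
                        "distance_um": float(np.linalg.norm(vec)),
                        "experiment": f"conf{ci}",
                    }
                )
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def msd_profile_um2(ensemble: EnsembleRecord, separations, scale: float):
    """Simulated <R^2>(s) converted to um^2 — convenience for comparing a
    synthetic FISH table back to the underlying ensemble."""
    prof = msd_profile(ensemble, separations)
    return prof.msd * scale**2
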