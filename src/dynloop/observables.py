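"""Ensemble observables: MSD vs contour distance, plateau compaction,
parameter-space heat maps and loop counts.

The central readout is the mean square spatial distance <R^2> between two
monomers as a function of their contour separation s.  Its saturation
(plateau) level measures overall polymer compaction: profiles can be
normalized by a reference plateau (MSD_ref) to compare looping regimes,
and a (p_short, p_long) scan of plateau levels yields the compaction heat
map.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import LatticeParams
from .loops import DomainLayout, LoopingParams, loop_stats
from .protocol import EnsembleRecord, ProtocolParams, run_protocol

__all__ = [
    "MSDProfile",
    "HeatMapGrid",
    "msd_profile",
    "plateau_level",
    "normalize_profile",
    "heatmap_scan",
    "mean_long_loop_count",
    "derive_cell_seed",
    "permutation_trend_pvalue",
]


@dataclass(frozen=True)
class MSDProfile:
    """<R^2>(s): mean squared spatial distance per contour separation.

    ``sem`` is the standard error over conformation-level means —
    conformations, not monomer pairs, are the independent units, because
    pairs within one conformation are strongly correlated.  ``n_monomers``
    records the chain length N the profile was measured on (needed to
    locate the plateau region).
    """

    separations: np.ndarray
    msd: np.ndarray
    sem: np.ndarray
    n_pairs: np.ndarray
    n_monomers: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "separation": self.separations,
                "msd": self.msd,
                "sem": self.sem,
                "n_pairs": self.n_pairs,
            }
        )

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_monomers: int | None = None) -> "MSDProfile":
        df = pd.read_csv(path, sep="\t")
        return cls(
            separations=df["separation"].to_numpy(),
            msd=df["msd"].to_numpy(dtype=float),
            sem=df["sem"].to_numpy(dtype=float),
            n_pairs=df["n_pairs"].to_numpy(),
            n_monomers=n_monomers,
        )


def msd_profile(ensemble: EnsembleRecord, separations=None) -> MSDProfile:
    """<R^2>(s) averaged over all monomer pairs at separation s and over
    all conformations, on unwrapped coordinates."""
    confs = ensemble.conformations
    if len(confs) < 2:
        raise ValueError("need at least 2 conformations")
    N = confs[0].N
    if separations is None:
        separations = np.arange(1, N)
    separations = np.asarray(separations, dtype=np.int64)
    if separations.min() < 1 or separations.max() > N - 1:
        raise ValueError("separations must lie in [1, N-1]")

    unwrapped = [c.unwrapped_positions().astype(np.float64) for c in confs]
    per_conf = np.empty((len(confs), len(separations)))
    for ci, pos in enumerate(unwrapped):
        for si, s in enumerate(separations):
            d = pos[s:] - pos[:-s]
            per_conf[ci, si] = (d**2).sum(axis=1).mean()
    msd = per_conf.mean(axis=0)
    sem = per_conf.std(axis=0, ddof=1) / math.sqrt(len(confs))
    n_pairs = (N - separations) * len(confs)
    return MSDProfile(separations=separations, msd=msd, sem=sem,
                      n_pairs=n_pairs, n_monomers=N)


def plateau_level(profile: MSDProfile, n_monomers: int | None = None) -> float:
    """Plateau of the MSD curve: the n_pairs-weighted mean of <R^2> over
    the top tercile of separations (s >= ceil(2N/3)).

    The profile must cover separations up to at least 0.8 N.
    """
    N = n_monomers if n_monomers is not None else profile.n_monomers
    if N is None:
        N = int(profile.separations.max()) + 1
    s = profile.separations
    if s.max() < 0.8 * N:
        raise ValueError(
            f"profile reaches s={s.max()} but plateau estimation needs "
            f"coverage up to 0.8*N={0.8 * N:.0f}"
        )
    mask = s >= math.ceil(2 * N / 3)
    if not mask.any():
        raise ValueError("no separations in the plateau region s >= 2N/3")
    w = profile.n_pairs[mask].astype(float)
    return float(np.average(profile.msd[mask], weights=w))


def normalize_profile(profile: MSDProfile, reference_plateau: float) -> MSDProfile:
    """Divide msd and sem by a reference plateau level (MSD_ref)."""
    if reference_plateau <= 0:
        raise ValueError("reference_plateau must be positive")
    return replace(
        profile,
        msd=profile.msd / reference_plateau,
        sem=profile.sem / reference_plateau,
    )


def mean_long_loop_count(ensemble: EnsembleRecord, c: int):
    """Mean and SEM over conformations of the long-loop count n_long
    (loops spanning more than c monomers)."""
    counts = np.array(
        [loop_stats(conf, c)[1] for conf in ensemble.conformations], dtype=float
    )
    if counts.size == 0:
        raise ValueError("empty ensemble")
    sem = counts.std(ddof=1) / math.sqrt(counts.size) if counts.size > 1 else 0.0
    return float(counts.mean()), float(sem)


def derive_cell_seed(base_seed: int, p_short: float, p_long: float) -> int:
    """Stable per-cell seed so heat-map scans are reproducible and
    order-independent."""
    key = f"{base_seed}:{p_short:.10g}:{p_long:.10g}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class HeatMapGrid:
    """Plateau-MSD values over a (p_short, p_long) grid."""

    p_short_values: np.ndarray
    p_long_values: np.ndarray
    plateau: np.ndarray  # shape (len(p_short), len(p_long))
    manifest: pd.DataFrame

    def to_long_frame(self) -> pd.DataFrame:
        return self.manifest.copy()

    def to_tsv(self, path):
        self.manifest.to_csv(path, sep="\t", index=False)


def heatmap_scan(p_short_values, p_long_values, *, N: int,
                 lattice: LatticeParams, looping: LoopingParams,
                 protocol: ProtocolParams, layout: DomainLayout | None = None,
                 out_dir=None) -> HeatMapGrid:
    """plateau_level over a grid of looping probabilities.

    Every cell reruns the full protocol with identical non-looping settings
    and a seed derived from (protocol.seed, p_short, p_long).  When
    ``out_dir`` is given, completed cells found in its manifest are skipped
    so interrupted scans resume.  Per-cell failures are recorded (NaN
    plateau) and the scan continues; a scan with no successful cell raises.
    """
    ps_values = np.asarray(p_short_values, dtype=float)
    pl_values = np.asarray(p_long_values, dtype=float)
    manifest_path = None
    done: dict[tuple[float, float], dict] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "heatmap_manifest.tsv"
        if manifest_path.exists():
            old = pd.read_csv(manifest_path, sep="\t")
            for row in old.to_dict("records"):
                done[(row["p_short"], row["p_long"])] = row

    rows = []
    plateau = np.full((len(ps_values), len(pl_values)), np.nan)
    n_ok = 0
    for i, ps in enumerate(ps_values):
        for j, pl in enumerate(pl_values):
            key = (float(ps), float(pl))
            if key in done:
                row = done[key]
            else:
                seed = derive_cell_seed(protocol.seed, ps, pl)
                cell_loop = replace(looping, p_short=float(ps), p_long=float(pl))
                cell_proto = replace(protocol, seed=seed)
                try:
                    ens = run_protocol(N, lattice, cell_loop, cell_proto,
                                       layout=layout)
                    prof = msd_profile(ens)
                    value = plateau_level(prof)
                    err = ""
                except Exception as exc:  # record and continue the scan
                    value = float("nan")
                    err = f"{type(exc).__name__}: {exc}"
                row = {
                    "p_short": float(ps),
                    "p_long": float(pl),
                    "plateau": value,
                    "n_conformations": protocol.n_conformations,
                    "seed": seed,
                    "error": err,
                }
                if manifest_path is not None:
                    header = not manifest_path.exists()
                    pd.DataFrame([row]).to_csv(
                        manifest_path, sep="\t", index=False, mode="a",
                        header=header,
                    )
            rows.append(row)
            plateau[i, j] = row["plateau"]
            if np.isfinite(row["plateau"]):
                n_ok += 1
    if n_ok == 0:
        raise RuntimeError("heat-map scan failed in every cell")
    return HeatMapGrid(
        p_short_values=ps_values,
        p_long_values=pl_values,
        plateau=plateau,
        manifest=pd.DataFrame(rows),
    )


def permutation_trend_pvalue(low, high, n_resamples: int = 20_000,
                             seed: int = 0) -> float:
    """One-sided test that mean(high) >= mean(low) is not a label-shuffling
    artifact: p-value of observing a mean difference at least as large
    under random reassignment of the per-seed values to the two cells.

    Enumerates all label assignments exactly when there are few (<= ~20k),
    otherwise Monte Carlo resamples.
    """
    low = np.asarray(low, dtype=float)
    high = np.asarray(high, dtype=float)
    pooled = np.concatenate([low, high])
    n_lo = low.size
    observed = high.mean() - low.mean()
    n_comb = math.comb(pooled.size, n_lo)
    if n_comb <= n_resamples:
        from itertools import combinations

        idx = np.arange(pooled.size)
        count = 0
        for lo_idx in combinations(idx, n_lo):
            lo_mask = np.zeros(pooled.size, dtype=bool)
            lo_mask[list(lo_idx)] = True
            diff = pooled[~lo_mask].mean() - pooled[lo_mask].mean()
            if diff >= observed - 1e-12:
                count += 1
        return count / n_comb
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        if perm[n_lo:].mean() - perm[:n_lo].mean() >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_resamples + 1)
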