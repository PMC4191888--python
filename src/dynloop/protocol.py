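"""Run schedule: SAW start, two-phase equilibration, production sampling.

A run starts from a random self-avoiding walk, first equilibrates with
homogeneous looping (a single probability for every eligible pair), then
with the target heterogeneous rule, and finally saves a conformation every
``save_interval`` MCS until at least ``n_conformations`` snapshots exist.
The squared radius of gyration is recorded at every save; its
autocorrelation time tau_ac (exponential fit to the normalized
autocorrelation function) gauges whether snapshots spaced >= 5 tau_ac apart
can be treated as statistically independent.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import BOND_VECTORS, Conformation, LatticeParams, init_saw
from .loops import DomainLayout, LoopingParams, _kernel_rule_args, events_to_frame

__all__ = [
    "ProtocolParams",
    "EnsembleRecord",
    "rg_squared",
    "autocorrelation_time",
    "run_protocol",
]

_MAX_LOGGED_EVENTS = 2_000_000


@dataclass(frozen=True)
class ProtocolParams:
    """MCS budgets and sampling schedule of a run.

    ``homogeneous_p`` is the phase-1 looping probability; when None it
    defaults to the mean of p_short and p_long — a neutral warm start
    between the two target regimes.
    """

    equil1_mcs: int = 20_000
    equil2_mcs: int = 20_000
    save_interval: int = 2_000
    n_conformations: int = 20
    seed: int = 0
    homogeneous_p: float | None = None

    def __post_init__(self):
        if min(self.equil1_mcs, self.equil2_mcs, self.save_interval) < 0:
            raise ValueError("MCS counts must be >= 0")
        if self.n_conformations < 1:
            raise ValueError("n_conformations >= 1 required")


@dataclass
class EnsembleRecord:
    """Saved production conformations with provenance."""

    conformations: list[Conformation]
    mcs_times: list[int]
    rg2: np.ndarray
    tau_ac: float | None
    config: dict
    seed: int
    notes: list[str] = field(default_factory=list)
    events: pd.DataFrame | None = None

    @property
    def N(self) -> int:
        return self.conformations[0].N

    def fingerprint(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def rg_squared(conf: Conformation) -> float:
    """Squared radius of gyration: mean squared distance of the monomers
    from their centroid, on backbone-unwrapped coordinates."""
    pos = conf.unwrapped_positions().astype(np.float64)
    centered = pos - pos.mean(axis=0)
    return float((centered**2).sum(axis=1).mean())


def autocorrelation_time(series, dt: float) -> float:
    """Autocorrelation time (in MCS) of a time series sampled every dt MCS.

    The normalized autocorrelation function is fitted with an exponential
    over its initial decay (lags with correlation above 0.05), by linear
    regression on the log.  White-noise-like series (no positive
    correlation at lag 1) return 0.0.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.size < 50:
        raise ValueError("need at least 50 samples to estimate tau_ac")
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("constant series: autocorrelation undefined")
    n = x.size
    acf = np.correlate(x, x, mode="full")[n - 1:] / var
    below = np.nonzero(acf < 0.05)[0]
    k_end = int(below[0]) if below.size else n
    lags = np.arange(k_end)
    mask = acf[lags] > 0
    lags = lags[mask]
    if lags.size < 2:  # immediate decorrelation
        return 0.0
    slope = np.polyfit(lags, np.log(acf[lags]), 1)[0]
    if slope >= 0:
        return 0.0
    return float(-dt / slope)


def _dummy_log():
    return (np.empty(0, np.int64), np.empty(0, np.int8), np.empty(0, np.int32),
            np.empty(0, np.int32), np.empty(0, np.int64))


def run_protocol(N: int, lattice: LatticeParams, looping: LoopingParams,
                 protocol: ProtocolParams, layout: DomainLayout | None = None,
                 *, log_events: bool = False) -> EnsembleRecord:
    """Execute the full schedule and return the production ensemble.

    All randomness derives from ``protocol.seed``: a master generator
    produces one kernel seed per simulation segment in a fixed order, so a
    run is exactly reproducible from its configuration.
    """
    if looping.mode == "domain_adapted" and layout is None:
        raise ValueError("domain_adapted looping requires a DomainLayout")
    code, p_s, p_l, block, linker = _kernel_rule_args(looping, layout, N)
    hom_p = (
        protocol.homogeneous_p
        if protocol.homogeneous_p is not None
        else 0.5 * (looping.p_short + looping.p_long)
    )

    master = np.random.default_rng(protocol.seed)
    conf = init_saw(N, lattice, int(master.integers(2**31)))
    partners = np.full((N, looping.max_bonds_per_monomer), -1, dtype=np.int32)
    expires = np.full((N, looping.max_bonds_per_monomer), -1, dtype=np.int64)
    anchor = conf.anchor_map()
    occ = conf.site_occupancy()

    all_events = []

    def segment(n_mcs, mode_code, ps, pl):
        if n_mcs == 0:
            return
        if log_events:
            cap = int(min(_MAX_LOGGED_EVENTS, 16 + 4 * n_mcs))
            bufs = (np.empty(cap, np.int64), np.empty(cap, np.int8),
                    np.empty(cap, np.int32), np.empty(cap, np.int32),
                    np.empty(cap, np.int64))
        else:
            cap = 0
            bufs = _dummy_log()
        # the per-MCS loop pass is skipped only when it can have no effect
        loops_on = ps > 0 or pl > 0 or bool((partners >= 0).any())
        n = _kernels.run_segment(
            conf.positions, anchor, occ, conf.L, BOND_VECTORS.table,
            BOND_VECTORS.half_array, partners, expires,
            mode_code, ps, pl, looping.short_cutoff, block, linker,
            looping.linkers_loop, looping.T_bond, loops_on,
            conf.mcs_clock, n_mcs, int(master.integers(2**31)),
            log_events, *bufs, 0,
        )
        conf.mcs_clock += n_mcs
        if log_events:
            if n >= cap:
                notes.append("event log truncated (buffer full)")
            all_events.append(events_to_frame(*(b[:n] for b in bufs)))

    notes: list[str] = []

    # phase 1: homogeneous equilibration
    segment(protocol.equil1_mcs, 0, hom_p, hom_p)
    # phase 2: equilibration under the target rule
    segment(protocol.equil2_mcs, code, p_s, p_l)

    # phase 3: production
    snapshots: list[Conformation] = []
    mcs_times: list[int] = []
    rg2: list[float] = []
    while len(snapshots) < protocol.n_conformations:
        segment(protocol.save_interval, code, p_s, p_l)
        conf.set_loop_bonds_from_arrays(partners, expires)
        snap = conf.copy()
        snapshots.append(snap)
        mcs_times.append(conf.mcs_clock)
        rg2.append(rg_squared(snap))

    rg2 = np.asarray(rg2)
    tau = None
    if len(rg2) >= 50 and rg2.std() > 0:
        tau = autocorrelation_time(rg2, protocol.save_interval)
        if protocol.save_interval < 5 * tau:
            msg = (
                f"save_interval={protocol.save_interval} < 5*tau_ac="
                f"{5 * tau:.0f} MCS: saved conformations are correlated; "
                f"thin by ~{int(np.ceil(5 * tau / protocol.save_interval))}x"
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)

    config = {
        "N": N,
        "lattice": {"L": lattice.L, "periodic": lattice.periodic},
        "looping": {
            "mode": looping.mode,
            "p_short": looping.p_short,
            "p_long": looping.p_long,
            "short_cutoff": looping.short_cutoff,
            "block_size": looping.block_size,
            "T_bond": looping.T_bond,
            "p_homogeneous": looping.p_homogeneous,
            "max_bonds_per_monomer": looping.max_bonds_per_monomer,
            "linkers_loop": looping.linkers_loop,
        },
        "protocol": {
            "equil1_mcs": protocol.equil1_mcs,
            "equil2_mcs": protocol.equil2_mcs,
            "save_interval": protocol.save_interval,
            "n_conformations": protocol.n_conformations,
            "seed": protocol.seed,
            "homogeneous_p": hom_p,
        },
        "layout": None if layout is None else {
            "n_domains": layout.n_domains,
            "n_linkers": layout.n_linkers,
            "block_size": layout.block_size,
        },
    }
    return EnsembleRecord(
        conformations=snapshots,
        mcs_times=mcs_times,
        rg2=rg2,
        tau_ac=tau,
        config=config,
        seed=protocol.seed,
        notes=notes,
        events=pd.concat(all_events, ignore_index=True) if all_events else None,
    )
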