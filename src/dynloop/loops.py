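"""Dynamic loop formation and dissociation.

Two spatially proximal, non-adjacent monomers can form a transient bond
("loop") with a probability p_bond,ij that depends either on their contour
separation (p_short within a cutoff, p_long beyond it) or on a layout of
alternating looped domains and inert linkers.  A formed bond receives a
Poisson-distributed lifetime with mean T_bond (in MCS) and dissociates when
that time is up; backbone bonds never break.  Loop updates run once per
MCS, after the N move attempts: dissociations first, then formation trials
over the currently proximal pairs in a shuffled order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import BOND_VECTORS, Conformation

__all__ = [
    "LoopBond",
    "LoopingParams",
    "DomainLayout",
    "build_domain_layout",
    "looping_probability",
    "sample_lifetime",
    "attempt_loop_updates",
    "loop_stats",
    "default_short_cutoff",
]

MODES = ("homogeneous", "uniform_adapted", "domain_adapted")
_MODE_CODE = {m: c for c, m in enumerate(MODES)}


@dataclass(frozen=True)
class LoopBond:
    """An active loop bond between monomers i < j, dissociating at the
    absolute MCS time ``expires_at``."""

    i: int
    j: int
    expires_at: int

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("LoopBond requires i < j")
        if self.j - self.i < 2:
            raise ValueError("loop bonds must span at least 2 monomers")


def default_short_cutoff(N: int) -> int:
    """Short/long contour cutoff scaled with polymer length: short loops
    span at most ~5% of the chain (50 of 1050 monomers at full scale)."""
    return max(2, round(0.05 * N))


@dataclass(frozen=True)
class LoopingParams:
    """Control parameters of the dynamic-loop rules.

    mode
        ``homogeneous`` — one probability for every eligible pair;
        ``uniform_adapted`` — p_short within ``short_cutoff`` monomers of
        contour separation, p_long beyond;
        ``domain_adapted`` — p_short inside a looped domain, p_long between
        looped domains, 0 when a linker monomer is involved (set
        ``linkers_loop`` to treat linkers as ordinary blocks instead).
    T_bond
        Mean Poisson bond lifetime in MCS (8000 at the full-scale preset).
    max_bonds_per_monomer
        Binding-site capacity; 1 by default (each monomer is one site).
    """

    mode: str = "uniform_adapted"
    p_short: float = 0.12
    p_long: float = 0.04
    short_cutoff: int = 50
    block_size: int = 50
    T_bond: float = 8000.0
    p_homogeneous: float = 0.08
    max_bonds_per_monomer: int = 1
    linkers_loop: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        for name in ("p_short", "p_long", "p_homogeneous"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.short_cutoff < 2:
            raise ValueError("short_cutoff >= 2 required")
        if self.block_size < 2:
            raise ValueError("block_size >= 2 required")
        if self.T_bond < 0:
            raise ValueError("T_bond >= 0 required")
        if self.max_bonds_per_monomer < 1:
            raise ValueError("max_bonds_per_monomer >= 1 required")

    @property
    def mode_code(self) -> int:
        return _MODE_CODE[self.mode]


@dataclass(frozen=True)
class DomainLayout:
    """Alternating blocks of looped domains and inert linkers.

    ``block_id`` gives each monomer its block index (0-based along the
    chain); ``is_linker`` flags linker monomers.  Looped domains are the
    odd-numbered blocks, so a layout always begins and ends with a linker.
    """

    block_id: np.ndarray
    is_linker: np.ndarray
    block_size: int = field(default=0)

    @property
    def n_domains(self) -> int:
        return len(np.unique(self.block_id[~self.is_linker.astype(bool)]))

    @property
    def n_linkers(self) -> int:
        return len(np.unique(self.block_id[self.is_linker.astype(bool)]))

    def domain_of(self, i: int) -> int | None:
        """Looped-domain index of monomer i, or None for a linker."""
        if self.is_linker[i]:
            return None
        return (int(self.block_id[i]) - 1) // 2


def build_domain_layout(N: int, b: int) -> DomainLayout:
    """Partition N monomers into alternating linker/domain blocks of b
    monomers, starting and ending with a linker: k looped domains and k+1
    linkers with N = b*(2k+1).  The full-scale chain (N=1050, b=50) has 10
    looped domains interspersed in 11 linkers."""
    if b < 2:
        raise ValueError("block size b >= 2 required")
    n_blocks, rem = divmod(N, b)
    if rem != 0 or n_blocks < 3 or n_blocks % 2 == 0:
        raise ValueError(
            f"N={N} incompatible with block size b={b}: need N = b*(2k+1) "
            f"with k >= 1 (an odd number >= 3 of equal blocks)"
        )
    block_id = np.repeat(np.arange(n_blocks), b).astype(np.int32)
    is_linker = (block_id % 2 == 0).astype(np.int8)
    return DomainLayout(block_id=block_id, is_linker=is_linker, block_size=b)


def looping_probability(i: int, j: int, params: LoopingParams,
                        layout: DomainLayout | None = None) -> float:
    """p_bond,ij for a non-adjacent pair under the configured rule."""
    if abs(i - j) < 2:
        raise ValueError(f"pair ({i}, {j}) is backbone-adjacent")
    if params.mode == "homogeneous":
        return params.p_homogeneous
    if params.mode == "uniform_adapted":
        return params.p_short if abs(i - j) <= params.short_cutoff else params.p_long
    if layout is None:
        raise ValueError("domain_adapted mode requires a DomainLayout")
    return float(
        _kernels.pair_probability(
            i, j, 2, params.p_short, params.p_long, params.short_cutoff,
            layout.block_id, layout.is_linker, params.linkers_loop,
        )
    )


def sample_lifetime(T_bond: float, rng: np.random.Generator) -> int:
    """Poisson bond lifetime (MCS) with mean T_bond."""
    if T_bond < 0:
        raise ValueError("T_bond >= 0 required")
    if T_bond == 0:
        return 0
    return int(rng.poisson(T_bond))


def _kernel_rule_args(params: LoopingParams, layout: DomainLayout | None, N: int):
    """Pack a LoopingParams/DomainLayout into kernel scalars and arrays."""
    code = params.mode_code
    if code == 0:
        p_s = p_l = params.p_homogeneous
    else:
        p_s, p_l = params.p_short, params.p_long
    if code == 2:
        if layout is None:
            raise ValueError("domain_adapted mode requires a DomainLayout")
        if layout.block_id.shape[0] != N:
            raise ValueError("layout size does not match monomer count")
        block, linker = layout.block_id, layout.is_linker
    else:
        block = np.zeros(N, dtype=np.int32)
        linker = np.zeros(N, dtype=np.int8)
    return code, p_s, p_l, block, linker


def attempt_loop_updates(conf: Conformation, params: LoopingParams,
                         layout: DomainLayout | None,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Run one dissociation-then-formation pass on ``conf`` in place.

    Expired bonds (expires_at <= mcs_clock) are removed; every proximal
    eligible pair then gets one Bernoulli formation trial.  Returns the
    event log as a DataFrame (mcs, event, i, j, lifetime).
    """
    N = conf.N
    code, p_s, p_l, block, linker = _kernel_rule_args(params, layout, N)
    partners, expires = conf.partner_arrays(params.max_bonds_per_monomer)
    if partners.shape[1] > params.max_bonds_per_monomer:
        raise ValueError("conformation already exceeds max_bonds_per_monomer")

    cap = 16 + N * len(BOND_VECTORS.half_array)
    log_mcs = np.empty(cap, dtype=np.int64)
    log_ev = np.empty(cap, dtype=np.int8)
    log_i = np.empty(cap, dtype=np.int32)
    log_j = np.empty(cap, dtype=np.int32)
    log_life = np.empty(cap, dtype=np.int64)

    n_half = len(BOND_VECTORS.half_array)
    cand_i = np.empty(N * n_half, dtype=np.int32)
    cand_j = np.empty(N * n_half, dtype=np.int32)
    order = np.empty(N * n_half, dtype=np.int64)
    _kernels.seed_rng(int(rng.integers(2**31)))
    n = _kernels.loop_update(
        conf.positions, conf.anchor_map(), conf.L, BOND_VECTORS.table,
        BOND_VECTORS.half_array, partners, expires,
        code, p_s, p_l, params.short_cutoff, block, linker,
        params.linkers_loop, params.T_bond, conf.mcs_clock,
        cand_i, cand_j, order,
        True, log_mcs, log_ev, log_i, log_j, log_life, 0,
    )
    conf.set_loop_bonds_from_arrays(partners, expires)
    return events_to_frame(log_mcs[:n], log_ev[:n], log_i[:n], log_j[:n],
                           log_life[:n])


def events_to_frame(mcs, ev, i, j, life) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mcs": np.asarray(mcs, dtype=np.int64),
            "event": np.where(np.asarray(ev) == _kernels.EV_FORM, "form", "break"),
            "i": np.asarray(i, dtype=np.int64),
            "j": np.asarray(j, dtype=np.int64),
            "lifetime": np.asarray(life, dtype=np.int64),
        }
    )


def loop_stats(conf: Conformation, c: int):
    """Counts of short (|i-j| <= c) and long loops plus the loop-size
    histogram; returns (n_short, n_long, sizes Series)."""
    sizes = np.array([j - i for (i, j) in conf.loop_bonds], dtype=np.int64)
    n_short = int((sizes <= c).sum())
    n_long = int((sizes > c).sum())
    hist = pd.Series(sizes).value_counts().sort_index() if len(sizes) else pd.Series(dtype=np.int64)
    return n_short, n_long, hist
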