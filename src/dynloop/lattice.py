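"""Self-avoiding lattice polymer with the classic 3D bond-fluctuation method.

Each monomer occupies a 2x2x2 cube of lattice sites identified by its
anchor corner; excluded volume forbids overlapping cubes, and bonds
(backbone and loop) are restricted to the 108 vectors obtained from
(2,0,0), (2,1,0), (2,1,1), (2,2,1), (3,0,0), (3,1,0) by coordinate
permutations and sign flips (squared lengths 4, 5, 6, 9, 10 — squared
length 8 is excluded,
which is what makes chain crossing impossible under single-site moves).
The lattice is periodic with edge L, chosen large enough that periodic
images never interact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "LatticeParams",
    "BondVectorSet",
    "Conformation",
    "allowed_bond_vectors",
    "init_saw",
    "attempt_move",
    "mcs_sweep",
    "validate_conformation",
    "proximal_pairs",
    "min_image",
    "unwrap_positions",
]

_BASE_VECTORS = ((2, 0, 0), (2, 1, 0), (2, 1, 1), (2, 2, 1), (3, 0, 0), (3, 1, 0))


@dataclass(frozen=True)
class LatticeParams:
    """Periodic cubic lattice of edge ``L`` sites per axis.

    ``L`` should be at least ~4x the expected radius of gyration so that a
    chain never feels its own periodic image; L >= 16 is enforced.
    """

    L: int
    periodic: bool = True

    def __post_init__(self):
        if self.L < 16:
            raise ValueError(f"lattice edge L={self.L} too small; L >= 16 required")
        if not self.periodic:
            raise ValueError("only periodic boundaries are supported")


class BondVectorSet:
    """The allowed bond vectors of the 3D bond-fluctuation method."""

    def __init__(self, vectors):
        self.vectors = frozenset(tuple(int(c) for c in v) for v in vectors)
        arr = np.array(sorted(self.vectors), dtype=np.int64)
        self.array = arr
        # (7,7,7) lookup table over components in [-3, 3]
        table = np.zeros((7, 7, 7), dtype=np.bool_)
        for v in self.vectors:
            table[v[0] + 3, v[1] + 3, v[2] + 3] = True
        self.table = table
        # one representative per {v, -v} pair, for single-count neighbor scans
        self.half_array = np.array(
            sorted(v for v in self.vectors if v > tuple(-c for c in v)),
            dtype=np.int64,
        )

    def __contains__(self, v):
        return tuple(int(c) for c in v) in self.vectors

    def __len__(self):
        return len(self.vectors)

    def __iter__(self):
        return iter(self.vectors)


def allowed_bond_vectors() -> BondVectorSet:
    """All 108 permutations/sign flips of the five base vectors."""
    vecs = set()
    for base in _BASE_VECTORS:
        for perm in itertools.permutations(base):
            for signs in itertools.product((1, -1), repeat=3):
                vecs.add(tuple(s * c for s, c in zip(signs, perm)))
    return BondVectorSet(vecs)


#: module-level singleton; the set is fixed by the method definition
BOND_VECTORS = allowed_bond_vectors()


def min_image(delta, L: int):
    """Component-wise minimum-image convention for integer displacements."""
    d = np.asarray(delta, dtype=np.int64)
    half = L // 2
    return (d + half) % L - half


@dataclass
class Conformation:
    """Positions of N monomer anchors plus the active loop bonds.

    ``positions`` are wrapped into [0, L); ``loop_bonds`` maps ordered pairs
    (i, j) with i < j to the absolute MCS time at which the bond dissociates.
    """

    positions: np.ndarray
    L: int
    mcs_clock: int = 0
    loop_bonds: dict = field(default_factory=dict)
    _anchor: np.ndarray | None = field(default=None, repr=False, compare=False)
    _occ: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def anchor_map(self) -> np.ndarray:
        """Flat L**3 map of anchor sites (lazy, kept in sync by
        attempt_move)."""
        if self._anchor is None:
            self._anchor = _kernels.build_anchor_map(self.positions, self.L)
        return self._anchor

    def site_occupancy(self) -> np.ndarray:
        """Flat L**3 0/1 map of all occupied cube sites (lazy, kept in
        sync by attempt_move)."""
        if self._occ is None:
            self._occ = _kernels.build_site_occupancy(self.positions, self.L)
        return self._occ

    def partner_arrays(self, max_bonds: int = 0):
        """Loop bonds as (N, K) partner/expiry arrays for the kernels."""
        counts = np.zeros(self.N, dtype=np.int64)
        for (i, j) in self.loop_bonds:
            counts[i] += 1
            counts[j] += 1
        K = max(int(max_bonds), int(counts.max()) if self.N else 0, 1)
        partners = np.full((self.N, K), -1, dtype=np.int32)
        expires = np.full((self.N, K), -1, dtype=np.int64)
        fill = np.zeros(self.N, dtype=np.int64)
        for (i, j), exp in sorted(self.loop_bonds.items()):
            partners[i, fill[i]] = j
            expires[i, fill[i]] = exp
            fill[i] += 1
            partners[j, fill[j]] = i
            expires[j, fill[j]] = exp
            fill[j] += 1
        return partners, expires

    def set_loop_bonds_from_arrays(self, partners, expires):
        bonds = {}
        for i in range(self.N):
            for k in range(partners.shape[1]):
                j = int(partners[i, k])
                if j > i:
                    bonds[(i, j)] = int(expires[i, k])
        self.loop_bonds = bonds

    def unwrapped_positions(self) -> np.ndarray:
        return unwrap_positions(self.positions, self.L)

    def copy(self) -> "Conformation":
        return Conformation(
            positions=self.positions.copy(),
            L=self.L,
            mcs_clock=self.mcs_clock,
            loop_bonds=dict(self.loop_bonds),
        )


def unwrap_positions(positions: np.ndarray, L: int) -> np.ndarray:
    """Remove periodic wrapping by accumulating minimum-image backbone bonds.

    Bond vectors are short (<= sqrt(10)), so the minimum image of each
    backbone step is unambiguous; the unwrapped chain starts at the stored
    position of monomer 0.
    """
    pos = np.asarray(positions, dtype=np.int64)
    steps = min_image(np.diff(pos, axis=0), L)
    out = np.empty_like(pos)
    out[0] = pos[0]
    np.cumsum(steps, axis=0, out=out[1:])
    out[1:] += pos[0]
    return out


def init_saw(N: int, lattice: LatticeParams, seed: int,
             max_restarts: int = 200) -> Conformation:
    """Grow a random self-avoiding walk of N monomers with no loop bonds.

    Growth picks a random allowed bond vector per step; if a step has no
    self-avoiding continuation the walk is restarted.  Raises RuntimeError
    after ``max_restarts`` failed growths (essentially impossible on a
    lattice respecting the L >= 4 Rg guideline).
    """
    if N < 2:
        raise ValueError("N >= 2 required")
    L = lattice.L
    rng = np.random.default_rng(seed)
    vecs = BOND_VECTORS.array
    neighborhood = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=np.int64)

    for _ in range(max_restarts):
        start = rng.integers(0, L, size=3)
        occupied = {tuple(start): 0}
        chain = [np.asarray(start, dtype=np.int64)]
        failed = False
        for m in range(1, N):
            order = rng.permutation(len(vecs))
            placed = False
            for vi in order:
                cand = (chain[-1] + vecs[vi]) % L
                # excluded volume: no anchor within Chebyshev distance 1
                if any(
                    tuple((cand + off) % L) in occupied for off in neighborhood
                ):
                    continue
                occupied[tuple(cand)] = m
                chain.append(cand)
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            return Conformation(positions=np.array(chain, dtype=np.int64), L=L)
    raise RuntimeError(
        f"self-avoiding walk growth failed after {max_restarts} restarts "
        f"(N={N}, L={L}); increase L or max_restarts"
    )


def attempt_move(conf: Conformation, rng: np.random.Generator,
                 *, monomer: int | None = None, direction: int | None = None):
    """One elementary Monte Carlo move attempt.

    A monomer and one of the 6 unit directions are chosen uniformly from
    ``rng`` (or forced via keywords, e.g. for enumerating outcomes).  The
    move is applied iff excluded volume holds at the target cube and every
    incident bond stays in the allowed set.  Returns (moved, monomer,
    direction).
    """
    m = int(rng.integers(conf.N)) if monomer is None else int(monomer)
    d = int(rng.integers(6)) if direction is None else int(direction)
    partners, _ = conf.partner_arrays()
    moved = _kernels.try_move(
        conf.positions, conf.anchor_map(), conf.site_occupancy(), conf.L,
        BOND_VECTORS.table, partners, m, d,
    )
    return bool(moved), m, d


def mcs_sweep(conf: Conformation, rng: np.random.Generator) -> Conformation:
    """One Monte Carlo step: N move attempts, then advance the MCS clock."""
    for _ in range(conf.N):
        attempt_move(conf, rng)
    conf.mcs_clock += 1
    return conf


def validate_conformation(conf: Conformation) -> list[str]:
    """Check every structural invariant; returns a list of violation
    messages (empty iff the conformation is valid)."""
    report: list[str] = []
    pos = conf.positions
    N, L = conf.N, conf.L
    if pos.min() < 0 or pos.max() >= L:
        report.append("positions outside [0, L)")

    occupied: dict[tuple, int] = {}
    for m in range(N):
        key = tuple(int(c) for c in pos[m])
        if key in occupied:
            report.append(f"coincident anchors: monomers {occupied[key]} and {m}")
        occupied[key] = m
    for m in range(N):
        for off in itertools.product((-1, 0, 1), repeat=3):
            if off == (0, 0, 0):
                continue
            other = occupied.get(tuple((pos[m] + np.array(off)) % L))
            if other is not None and other > m:
                report.append(f"excluded-volume overlap: monomers {m} and {other}")

    for m in range(N - 1):
        v = tuple(min_image(pos[m + 1] - pos[m], L))
        if v not in BOND_VECTORS:
            report.append(f"illegal backbone bond vector {v} at ({m}, {m + 1})")

    for (i, j), exp in conf.loop_bonds.items():
        if not (0 <= i < j < N):
            report.append(f"loop bond index out of range: ({i}, {j})")
            continue
        if j - i < 2:
            report.append(f"loop bond between adjacent monomers: ({i}, {j})")
        v = tuple(min_image(pos[j] - pos[i], L))
        if v not in BOND_VECTORS:
            report.append(f"illegal loop bond vector {v} at ({i}, {j})")
    return report


def proximal_pairs(conf: Conformation) -> set[tuple[int, int]]:
    """All unordered non-adjacent pairs whose separation is an allowed bond
    vector — the candidates for loop formation.

    Uses the anchor occupancy map as a spatial hash: for each monomer only
    the 54 sites one half-set of bond vectors away are probed, which is
    equivalent to (and tested against) the all-pairs scan.
    """
    anchor = conf.anchor_map()
    pos, L = conf.positions, conf.L
    pairs: set[tuple[int, int]] = set()
    for i in range(conf.N):
        probes = (pos[i] + BOND_VECTORS.half_array) % L
        flat = (probes[:, 0] * L + probes[:, 1]) * L + probes[:, 2]
        js = anchor[flat]
        for j in js[js >= 0]:
            j = int(j)
            if abs(i - j) >= 2:
                pairs.add((min(i, j), max(i, j)))
    return pairs
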