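import numpy as np
import pytest

from dynloop import (
    Conformation,
    LatticeParams,
    init_saw,
    mcs_sweep,
    run_protocol,
    test_preset,
)
from dynloop.lattice import BOND_VECTORS, min_image


def straight_rod(n: int, L: int = 64, spacing=(2, 0, 0)) -> Conformation:
    """Rod conformation with identical backbone bond vectors."""
    start = np.array([4, 4, 4], dtype=np.int64)
    pos = start + np.arange(n)[:, None] * np.array(spacing, dtype=np.int64)
    return Conformation(positions=pos % L, L=L)


def brute_force_proximal_pairs(conf: Conformation) -> set:
    """O(N^2) oracle for loop-candidate pairs."""
    pairs = set()
    pos, L = conf.positions, conf.L
    for i in range(conf.N):
        for j in range(i + 2, conf.N):
            v = tuple(min_image(pos[j] - pos[i], L))
            if v in BOND_VECTORS:
                pairs.add((i, j))
    return pairs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def random_conformations():
    """A bag of small random conformations: SAWs evolved by a few sweeps."""
    lat = LatticeParams(L=32)
    confs = []
    for seed in range(10):
        conf = init_saw(40, lat, seed=seed)
        sweep_rng = np.random.default_rng(1000 + seed)
        for _ in range(5):
            mcs_sweep(conf, sweep_rng)
        confs.append(conf)
    return confs


@pytest.fixture(scope="session")
def uniform_ensemble():
    """Small equilibrated ensemble under the contour-cutoff rule."""
    cfg = test_preset(seed=11)
    from dataclasses import replace

    proto = replace(cfg.protocol, equil1_mcs=10_000, equil2_mcs=20_000,
                    save_interval=2_000, n_conformations=12)
    return run_protocol(cfg.N, cfg.lattice, cfg.looping, proto)


@pytest.fixture(scope="session")
def domain_ensemble():
    """Small equilibrated ensemble under the domain-layout rule."""
    cfg = test_preset(seed=12, mode="domain_adapted")
    from dataclasses import replace

    proto = replace(cfg.protocol, equil1_mcs=10_000, equil2_mcs=20_000,
                    save_interval=2_000, n_conformations=12)
    return run_protocol(cfg.N, cfg.lattice, cfg.looping, proto,
                        layout=cfg.layout())
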