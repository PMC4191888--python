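"""Bond-fluctuation lattice: allowed vectors, moves, excluded volume."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynloop import (
    Conformation,
    LatticeParams,
    allowed_bond_vectors,
    attempt_move,
    init_saw,
    mcs_sweep,
    proximal_pairs,
    validate_conformation,
)
from dynloop.lattice import BOND_VECTORS, min_image, unwrap_positions

from conftest import brute_force_proximal_pairs, straight_rod


class TestBondVectors:
    def test_classic_set_has_108_vectors(self):
        bv = allowed_bond_vectors()
        assert len(bv) == 108

    @pytest.mark.parametrize("vector,member", [
        ((2, 0, 0), True),
        ((3, 1, 0), True),
        ((2, 2, 1), True),
        ((-2, 1, -1), True),
        ((2, 2, 0), False),   # squared length 8: would allow chain crossing
        ((1, 0, 0), False),   # below the minimum bond length 2
        ((3, 1, 1), False),   # squared length 11: too long
        ((0, 0, 0), False),
    ])
    def test_membership(self, vector, member):
        assert (vector in BOND_VECTORS) is member

    def test_squared_lengths(self):
        lengths = {sum(c * c for c in v) for v in BOND_VECTORS}
        assert lengths == {4, 5, 6, 9, 10}

    def test_closed_under_sign_flips_and_permutations(self):
        import itertools

        for v in BOND_VECTORS:
            for perm in itertools.permutations(v):
                for signs in itertools.product((1, -1), repeat=3):
                    assert tuple(s * c for s, c in zip(signs, perm)) in BOND_VECTORS

    def test_half_set_covers_all_without_double_count(self):
        half = {tuple(v) for v in BOND_VECTORS.half_array}
        assert len(half) == 54
        assert half | {tuple(-c for c in v) for v in half} == BOND_VECTORS.vectors


class TestInitSaw:
    def test_valid_and_deterministic(self):
        lat = LatticeParams(L=64)
        a = init_saw(100, lat, seed=7)
        b = init_saw(100, lat, seed=7)
        assert validate_conformation(a) == []
        assert np.array_equal(a.positions, b.positions)
        assert a.loop_bonds == {}

    def test_different_seed_differs(self):
        lat = LatticeParams(L=64)
        a = init_saw(100, lat, seed=7)
        c = init_saw(100, lat, seed=8)
        assert not np.array_equal(a.positions, c.positions)

    def test_dimer_bond_is_allowed_vector(self):
        conf = init_saw(2, LatticeParams(L=64), seed=1)
        v = tuple(min_image(conf.positions[1] - conf.positions[0], 64))
        assert v in BOND_VECTORS

    def test_too_small_N_rejected(self):
        with pytest.raises(ValueError):
            init_saw(1, LatticeParams(L=64), seed=0)

    def test_dense_growth_fails_explicitly(self):
        # N monomers need 8N sites plus wiggle room; an L=16 lattice cannot
        # host a 600-monomer chain and growth must fail loudly.
        with pytest.raises(RuntimeError, match="growth failed"):
            init_saw(600, LatticeParams(L=16), seed=0, max_restarts=3)


class TestAttemptMove:
    def dimer(self):
        pos = np.array([[10, 10, 10], [12, 10, 10]], dtype=np.int64)
        return Conformation(positions=pos, L=64)

    @pytest.mark.parametrize("direction,accepted", [
        (0, True),    # +x: separation becomes (3,0,0)
        (1, False),   # -x: separation (1,0,0) is not an allowed bond
        (2, True),    # +y: (2,1,0)
        (3, True),    # -y: (2,-1,0)
        (4, True),    # +z: (2,0,1)
        (5, True),    # -z: (2,0,-1)
    ])
    def test_dimer_direction_outcomes(self, direction, accepted):
        # brute-force enumeration of all 6 proposals for monomer 1 of a
        # dimer bonded by (2,0,0): only -x (separation (1,0,0)) is illegal
        conf = self.dimer()
        moved, *_ = attempt_move(conf, np.random.default_rng(0),
                                 monomer=1, direction=direction)
        assert moved is accepted
        assert validate_conformation(conf) == []

    def test_rejected_move_leaves_state_unchanged(self):
        conf = self.dimer()
        before = conf.positions.copy()
        moved, *_ = attempt_move(conf, np.random.default_rng(0),
                                 monomer=1, direction=1)
        assert not moved
        assert np.array_equal(conf.positions, before)

    def test_excluded_volume_rejection_with_legal_bonds(self):
        # chain folded so monomer 3 sits two sites from monomer 0; moving 3
        # in -y keeps its bond to 2 legal ((2,1,0)) but would put its cube
        # within Chebyshev distance 1 of monomer 0's cube
        pos = np.array(
            [[10, 10, 10], [12, 10, 10], [12, 12, 11], [10, 12, 11]],
            dtype=np.int64,
        )
        conf = Conformation(positions=pos, L=64)
        assert validate_conformation(conf) == []
        moved, *_ = attempt_move(conf, np.random.default_rng(0),
                                 monomer=3, direction=3)  # -y
        assert not moved
        assert np.array_equal(conf.positions, pos)

    def test_single_site_moves_are_reversible(self):
        conf = self.dimer()
        moved, *_ = attempt_move(conf, np.random.default_rng(0),
                                 monomer=1, direction=2)  # +y
        assert moved
        back, *_ = attempt_move(conf, np.random.default_rng(0),
                                 monomer=1, direction=3)  # -y undoes it
        assert back
        assert np.array_equal(conf.positions, self.dimer().positions)

    def test_loop_bond_constrains_moves(self):
        # monomers 0 and 2 are loop-bonded at separation (3,0,0); moving
        # monomer 2 in +x keeps the backbone bond legal ((2,-2,-1)) and
        # violates no excluded volume, but would stretch the loop to the
        # illegal (4,0,0) -- so the move must be rejected, and accepted
        # once the loop bond is removed
        pos = np.array([[10, 10, 10], [12, 12, 11], [13, 10, 10]],
                       dtype=np.int64)
        conf = Conformation(positions=pos, L=64,
                            loop_bonds={(0, 2): 10**9})
        assert validate_conformation(conf) == []
        moved, *_ = attempt_move(conf, np.random.default_rng(0),
                                 monomer=2, direction=0)  # +x
        assert not moved

        free = Conformation(positions=pos.copy(), L=64)
        moved, *_ = attempt_move(free, np.random.default_rng(0),
                                 monomer=2, direction=0)
        assert moved


class TestMcsSweep:
    def test_sweep_advances_clock_and_attempts_N_moves(self, monkeypatch):
        import dynloop.lattice as lattice_mod

        conf = init_saw(10, LatticeParams(L=32), seed=3)
        calls = {"n": 0}
        original = lattice_mod.attempt_move

        def counting(conf, rng, **kw):
            calls["n"] += 1
            return original(conf, rng, **kw)

        monkeypatch.setattr(lattice_mod, "attempt_move", counting)
        lattice_mod.mcs_sweep(conf, np.random.default_rng(0))
        assert calls["n"] == 10
        assert conf.mcs_clock == 1

    def test_frozen_sweep_only_advances_clock(self, monkeypatch):
        import dynloop.lattice as lattice_mod

        conf = init_saw(10, LatticeParams(L=32), seed=3)
        before = conf.positions.copy()
        monkeypatch.setattr(lattice_mod, "attempt_move",
                            lambda conf, rng, **kw: (False, 0, 0))
        lattice_mod.mcs_sweep(conf, np.random.default_rng(0))
        assert np.array_equal(conf.positions, before)
        assert conf.mcs_clock == 1

    def test_invariants_hold_over_many_sweeps(self):
        conf = init_saw(50, LatticeParams(L=32), seed=5)
        rng = np.random.default_rng(50)
        for sweep in range(100):
            mcs_sweep(conf, rng)
            assert validate_conformation(conf) == []
        assert conf.mcs_clock == 100


class TestValidateConformation:
    def test_overlap_reported(self):
        pos = np.array([[10, 10, 10], [11, 10, 10]], dtype=np.int64)
        report = validate_conformation(Conformation(positions=pos, L=64))
        assert any("overlap" in r or "coincident" in r for r in report)

    def test_coincident_monomers_reported(self):
        pos = np.array([[10, 10, 10], [12, 10, 10], [10, 10, 10]],
                       dtype=np.int64)
        report = validate_conformation(Conformation(positions=pos, L=64))
        assert any("coincident" in r for r in report)

    def test_adjacent_loop_bond_reported(self):
        conf = straight_rod(6)
        conf.loop_bonds = {(3, 4): 100}
        report = validate_conformation(conf)
        assert any("adjacent" in r for r in report)

    def test_illegal_loop_vector_reported(self):
        conf = straight_rod(6)  # monomers 0 and 2 are (4,0,0) apart
        conf.loop_bonds = {(0, 2): 100}
        report = validate_conformation(conf)
        assert any("illegal loop bond" in r for r in report)


class TestProximalPairs:
    def test_straight_rod_has_no_candidates(self):
        conf = straight_rod(10)
        assert proximal_pairs(conf) == set()
        assert brute_force_proximal_pairs(conf) == set()

    def test_separation_4_not_proximal(self):
        pos = np.array([[10, 10, 10], [12, 11, 11], [14, 10, 10]],
                       dtype=np.int64)
        conf = Conformation(positions=pos, L=64)
        assert (0, 2) not in proximal_pairs(conf)

    def test_folded_chain_matches_brute_force(self):
        pos = np.array(
            [[10, 10, 10], [12, 10, 10], [12, 12, 11], [10, 12, 11]],
            dtype=np.int64,
        )
        conf = Conformation(positions=pos, L=64)
        pairs = proximal_pairs(conf)
        assert pairs == brute_force_proximal_pairs(conf)
        assert (0, 3) in pairs  # separation (0,2,1) is an allowed vector

    def test_matches_brute_force_on_random_conformations(
            self, random_conformations):
        for conf in random_conformations:
            assert proximal_pairs(conf) == brute_force_proximal_pairs(conf)

    def test_periodic_wrap_pairs_detected(self):
        # neighbors across the periodic boundary
        pos = np.array([[1, 10, 10], [3, 11, 11], [31, 10, 10]],
                       dtype=np.int64)
        conf = Conformation(positions=pos, L=32)
        assert (0, 2) in proximal_pairs(conf)  # separation wraps to (2,0,0)


class TestUnwrap:
    def test_unwrap_restores_straight_rod_across_boundary(self):
        L = 32
        pos = (np.array([4, 4, 4]) + np.arange(20)[:, None] * np.array([2, 0, 0])) % L
        out = unwrap_positions(pos, L)
        steps = np.diff(out, axis=0)
        assert np.all(steps == np.array([2, 0, 0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_unwrapped_backbone_steps_equal_min_image(self, seed):
        conf = init_saw(20, LatticeParams(L=32), seed=seed)
        out = unwrap_positions(conf.positions, 32)
        expected = min_image(np.diff(conf.positions, axis=0), 32)
        assert np.array_equal(np.diff(out, axis=0), expected)
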