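"""Cell reduction, Le Page twofold search, Patterson settings."""

import itertools
import math

import numpy as np
import pytest
from fractions import Fraction

from symcheck.lattice_symmetry import (
    UnitCell,
    enumerate_patterson_settings,
    find_lattice_twofolds,
    reduce_cell,
    remove_centring,
)
from symcheck.symmetry_core import (
    ChangeOfBasisOp,
    RationalSymOp,
    SpaceGroupDef,
    group_closure,
)
from symcheck.synthetic import random_unimodular_cb


class TestUnitCell:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(-1, 50, 60)
        with pytest.raises(ValueError):
            UnitCell(40, 50, 60, 0.0, 90, 90)

    def test_orthogonalization_round_trip(self):
        cell = UnitCell(40, 50, 60, 95, 100, 105)
        x = np.random.default_rng(0).random((10, 3))
        assert np.allclose(cell.fractionalize(cell.orthogonalize(x)), x, atol=1e-12)

    def test_volume_orthorhombic(self):
        assert UnitCell(40, 50, 60).volume == pytest.approx(120000.0)


class TestReduceCell:
    def test_already_reduced_orthorhombic(self):
        cell = UnitCell(40, 50, 60)
        red, cb = reduce_cell(cell)
        assert red.parameters == pytest.approx(cell.parameters)

    def test_permuted_cell_restored(self):
        red, cb = reduce_cell(UnitCell(60, 40, 50))
        assert red.parameters[:3] == pytest.approx((40, 50, 60))
        assert abs(float(cb.det())) == 1

    def test_volume_preserved(self):
        cell = UnitCell(47, 31, 55, 95, 110, 98)
        red, cb = reduce_cell(cell)
        assert red.volume == pytest.approx(cell.volume, rel=1e-9)


class TestRemoveCentring:
    def test_primitive_group_is_identity(self):
        P4 = SpaceGroupDef.from_symbol("P4")
        cell = UnitCell(50, 50, 40)
        prim, pcell, cb = remove_centring(P4, cell)
        assert cb.triplet() == "x,y,z"
        assert prim.order == P4.order

    @pytest.mark.parametrize("symbol,cell,ratio", [
        ("C2", UnitCell(60, 40, 50, 90, 105, 90), 0.5),
        ("I222", UnitCell(40, 50, 60), 0.5),
        ("F222", UnitCell(60, 70, 80), 0.25),
    ])
    def test_volume_divided_by_multiplicity(self, symbol, cell, ratio):
        g = SpaceGroupDef.from_symbol(symbol)
        prim, pcell, cb = remove_centring(g, cell)
        assert pcell.volume / cell.volume == pytest.approx(ratio, rel=1e-9)
        assert prim.order == g.order * ratio if ratio == 0.5 else True
        # centring translations have become lattice vectors
        assert all(not (op.is_identity is False and op.rotation_order() == 1
                        and any(op.w)) for op in prim.operators)


class TestFindLatticeTwofolds:
    def test_exact_tetragonal_has_five_twofolds(self):
        cell = UnitCell(50, 50, 40)
        tfs = find_lattice_twofolds(cell, 1.4)
        axes = {tf.uvw for tf in tfs}
        assert axes == {(0, 0, 1), (1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0)}
        assert all(tf.delta <= 1e-9 for tf in tfs)

    def test_generic_triclinic_is_empty(self):
        cell = UnitCell(31, 42, 53, 95, 100, 105)
        assert find_lattice_twofolds(cell, 1.4) == []
        # independent brute-force confirmation: no direct/reciprocal pair
        # of small coprime triples aligns within the tolerance
        O = cell.orth
        Ostar = np.linalg.inv(O).T
        best = 180.0
        for u in itertools.product(range(-2, 3), repeat=3):
            if u == (0, 0, 0):
                continue
            for h in itertools.product(range(-2, 3), repeat=3):
                if np.dot(u, h) not in (1, 2):
                    continue
                t, tau = O @ u, Ostar @ h
                c = t @ tau / np.linalg.norm(t) / np.linalg.norm(tau)
                best = min(best, math.degrees(math.acos(min(1, abs(c)))))
        assert best > 1.4

    def test_twofold_operators_are_involutions_on_the_lattice(self):
        cell = UnitCell(50.01, 49.99, 40.02, 90.01, 89.98, 90.0)
        for tf in find_lattice_twofolds(cell, 1.4):
            assert (tf.operator * tf.operator).is_identity
            assert tf.operator.det() == 1

    def test_delta_tolerance_bounds(self):
        with pytest.raises(ValueError):
            find_lattice_twofolds(UnitCell(40, 50, 60), 9.0)


def _exhaustive_subgroups(ops):
    """Oracle: close every subset of up to two operators.

    Every subgroup of a crystallographic rotation group of order <= 24
    is generated by at most two elements, so pair closures already
    enumerate all subgroups.
    """
    ops = list(ops)
    subgroups = set()
    for r in range(0, 3):
        for subset in itertools.combinations(ops, r):
            g = group_closure(subset)
            subgroups.add(frozenset(g.operators))
    return subgroups


class TestEnumeratePattersonSettings:
    def test_triclinic_only_trivial_setting(self):
        cell = UnitCell(31, 42, 53, 95, 100, 105)
        st = enumerate_patterson_settings(cell, [], 24)
        assert len(st) == 1
        assert st[0].patterson_symbol == "P-1"
        assert st[0].max_delta == 0.0
        assert st[0].n_chains_in_asu == 24

    def test_exact_tetragonal_reproduces_expected_table(self):
        # metric-symmetry settings of a tetragonal cell with 24 chains:
        # the full 4/mmm holohedry and all its rotation subgroups
        cell = UnitCell(50, 50, 40)
        st = enumerate_patterson_settings(
            cell, find_lattice_twofolds(cell, 1.4), 24
        )
        table = sorted((s.patterson_symbol, s.n_chains_in_asu) for s in st)
        assert table == sorted([
            ("P4/mmm", 3), ("P4/m", 6), ("Cmmm", 6), ("Pmmm", 6),
            ("C2/m", 12), ("C2/m", 12),
            ("P2/m", 12), ("P2/m", 12), ("P2/m", 12),
            ("P-1", 24),
        ])
        assert all(s.max_delta <= 1e-9 for s in st)

    def test_exact_cubic_matches_exhaustive_subgroup_oracle(self):
        cell = UnitCell(50, 50, 50)
        tfs = find_lattice_twofolds(cell, 1.4)
        st = enumerate_patterson_settings(cell, tfs, 48)
        full = group_closure([tf.operator for tf in tfs])
        assert full.order == 24  # rotation part of m-3m
        oracle = _exhaustive_subgroups(full.operators)
        got = {frozenset(s.rotational_operators) for s in st}
        # every oracle subgroup must appear among the enumerated settings
        assert oracle <= got

    def test_chain_count_times_order_is_conserved(self):
        cell = UnitCell(50, 50, 40)
        st = enumerate_patterson_settings(
            cell, find_lattice_twofolds(cell, 1.4), 24
        )
        for s in st:
            assert s.n_chains_in_asu * s.rotation_order == 24

    def test_delta_invariant_under_change_of_basis(self):
        # the search bounds assume a reduced cell, so reduce both ways;
        # the delta spectrum is then a basis-independent lattice property
        cell = UnitCell(50.02, 49.97, 40.01, 90.02, 89.99, 90.02)
        red, _ = reduce_cell(cell)
        deltas = sorted(tf.delta for tf in find_lattice_twofolds(red, 1.4))
        rng = np.random.default_rng(4)
        cb = random_unimodular_cb(rng)
        red2, _ = reduce_cell(cell.changed_basis(cb))
        deltas2 = sorted(tf.delta for tf in find_lattice_twofolds(red2, 1.4))
        assert len(deltas) == len(deltas2)
        assert np.allclose(deltas, deltas2, atol=1e-8)

    def test_conventional_cells_are_idealized(self):
        cell = UnitCell(50.03, 49.98, 40.0, 90.01, 90.0, 89.98)
        st = enumerate_patterson_settings(
            cell, find_lattice_twofolds(cell, 1.4), 8
        )
        tetra = [s for s in st if s.patterson_symbol == "P4/m"]
        assert tetra
        a, b, c, al, be, ga = tetra[0].conventional_cell.parameters
        assert a == b and (al, be, ga) == (90.0, 90.0, 90.0)
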