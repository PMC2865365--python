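"""Structure factors, P1 expansion/merging, R_symop."""

import numpy as np
import pytest

from symcheck.intensities import (
    NoPairsError,
    ReflectionSet,
    calc_structure_factors,
    expand_obs_to_p1,
    friedel_canonical,
    hemisphere_indices,
    merge_under_group,
    r_symop,
    score_patterson_settings,
)
from symcheck.lattice_symmetry import (
    UnitCell,
    enumerate_patterson_settings,
    find_lattice_twofolds,
)
from symcheck.model import ScattererModel
from symcheck.symmetry_core import RationalSymOp, SpaceGroupDef

Op = RationalSymOp


class TestHemisphere:
    def test_friedel_unique_and_resolution_limited(self):
        cell = UnitCell(20, 25, 30)
        H = hemisphere_indices(cell, 4.0)
        assert np.all(cell.d_spacing(H) >= 4.0)
        # canonical hemisphere: no index and its Friedel mate both present
        s = {tuple(h) for h in H}
        assert not any(tuple(-np.array(h)) in s for h in s)
        assert np.array_equal(friedel_canonical(H), H)

    def test_count_scales_with_volume(self):
        small = len(hemisphere_indices(UnitCell(20, 20, 20), 4.0))
        big = len(hemisphere_indices(UnitCell(40, 40, 40), 4.0))
        assert big / small == pytest.approx(8.0, rel=0.2)


class TestCalcStructureFactors:
    def test_matches_slow_reference_sum(self):
        """Independent oracle: naive python loop over atoms and indices."""
        rng = np.random.default_rng(7)
        cell = UnitCell(14, 17, 12, 90, 101, 90)
        sites = rng.random((6, 3))
        b = rng.uniform(5, 25, size=6)
        occ = rng.uniform(0.5, 1.0, size=6)
        model = ScattererModel(cell, sites, occupancy=occ, b_iso=b)
        fs = calc_structure_factors(model, 4.0)
        for H, F in zip(fs.hkl[::7], fs.F[::7]):
            s2 = 1.0 / cell.d_spacing(H[None, :])[0] ** 2
            ref = sum(
                occ[j] * np.exp(-0.25 * b[j] * s2)
                * np.exp(2j * np.pi * (H @ sites[j]))
                for j in range(6)
            )
            assert abs(F - ref) <= 1e-8 * max(1.0, abs(ref))

    def test_intensities_are_squared_amplitudes(self):
        model = ScattererModel(UnitCell(15, 15, 15), [[0.1, 0.2, 0.3]])
        fs = calc_structure_factors(model, 5.0)
        assert np.allclose(fs.I, np.abs(fs.F) ** 2, atol=1e-12)
        # single atom: every amplitude is exactly 1
        assert np.allclose(np.abs(fs.F), 1.0, atol=1e-12)

    def test_origin_atom_gives_zero_phase(self):
        model = ScattererModel(UnitCell(15, 15, 15), [[0.0, 0.0, 0.0]])
        fs = calc_structure_factors(model, 5.0)
        assert np.allclose(fs.F.imag, 0.0, atol=1e-12)
        assert np.allclose(fs.F.real, 1.0, atol=1e-12)


class TestReflectionSet:
    def test_duplicate_indices_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ReflectionSet(UnitCell(20, 20, 20), SpaceGroupDef.from_symbol("P1"),
                          [(1, 0, 0), (1, 0, 0)], [1.0, 2.0])

    def test_lookup_handles_friedel_mates(self):
        rs = ReflectionSet(UnitCell(20, 20, 20), SpaceGroupDef.from_symbol("P1"),
                           [(1, 2, 3), (2, 0, 1)], [5.0, 7.0])
        idx, found = rs.lookup(np.array([(-1, -2, -3), (2, 0, 1), (4, 4, 4)]))
        assert list(found) == [True, True, False]
        assert idx[0] == 0 and idx[1] == 1


class TestExpandAndMerge:
    def test_expand_then_merge_round_trip(self, p4_scatterers):
        P4 = SpaceGroupDef.from_symbol("P4")
        fs = calc_structure_factors(p4_scatterers, 3.5)
        merged = merge_under_group(fs, P4)
        expanded, n_clip = expand_obs_to_p1(merged)
        assert n_clip == 0
        remerged = merge_under_group(expanded, P4)
        assert np.array_equal(remerged.hkl, merged.hkl)
        assert np.allclose(remerged.I, merged.I, rtol=1e-12)

    def test_orbit_sizes_shrink_reflection_count(self, p4_scatterers):
        P4 = SpaceGroupDef.from_symbol("P4")
        fs = calc_structure_factors(p4_scatterers, 3.5)
        merged = merge_under_group(fs, P4)
        # a general orbit has 4 Friedel-unique members; axis/zone
        # reflections with smaller orbits pull the mean ratio below 4
        ratio = fs.n_reflections / merged.n_reflections
        assert 3.0 < ratio <= 4.0

    def test_negative_intensities_clipped_and_counted(self):
        rs = ReflectionSet(UnitCell(20, 20, 20), SpaceGroupDef.from_symbol("P112"),
                           [(1, 2, 3), (2, 0, 1)], [-1.0, 7.0])
        expanded, n_clip = expand_obs_to_p1(rs)
        assert n_clip == 1
        assert np.all(expanded.I >= 0)


class TestRSymop:
    def test_true_operator_scores_zero(self, p4_scatterers):
        fs = calc_structure_factors(p4_scatterers, 3.5)
        r, n = r_symop(fs, Op.from_triplet("-y,x,z"))
        assert r <= 1e-12
        assert n > 100

    def test_matches_two_line_oracle_on_random_data(self):
        rng = np.random.default_rng(1)
        model = ScattererModel(UnitCell(18, 18, 14), rng.random((8, 3)))
        fs = calc_structure_factors(model, 3.5)
        op = Op.from_triplet("-y,x,z")
        r, n = r_symop(fs, op)
        # oracle: explicit pairing by dictionary
        table = {tuple(h): v for h, v in zip(fs.hkl, fs.I)}
        num = den = 0.0
        cnt = 0
        for h, v in table.items():
            hw = tuple(friedel_canonical(op.apply_to_miller(np.array([h])))[0])
            if hw == h or hw not in table:
                continue
            num += abs(v - table[hw])
            den += v + table[hw]
            cnt += 1
        assert r == pytest.approx(num / den, rel=1e-12)
        assert n == cnt // 2
        # unrelated pairing sits far above the 25% acceptance level
        assert r > 0.3

    def test_symmetric_under_inverse(self, p4_scatterers):
        rng = np.random.default_rng(2)
        model = ScattererModel(p4_scatterers.cell,
                               np.mod(p4_scatterers.sites +
                                      rng.normal(0, 0.01, p4_scatterers.sites.shape), 1))
        fs = calc_structure_factors(model, 3.5)
        four = Op.from_triplet("-y,x,z")
        r1, n1 = r_symop(fs, four)
        r2, n2 = r_symop(fs, four.inverse())
        assert r1 == pytest.approx(r2, rel=1e-12)
        assert n1 == n2

    def test_scale_invariance(self, p4_scatterers):
        fs = calc_structure_factors(p4_scatterers, 4.0)
        noisy = ReflectionSet(fs.cell, fs.symmetry, fs.hkl,
                              fs.I + 0.05 * fs.I.mean())
        scaled = ReflectionSet(fs.cell, fs.symmetry, fs.hkl, noisy.I * 123.0)
        op = Op.from_triplet("-y,x,z")
        assert r_symop(noisy, op)[0] == pytest.approx(r_symop(scaled, op)[0],
                                                      rel=1e-12)

    def test_monotone_in_noise(self, p4_scatterers):
        op = Op.from_triplet("-y,x,z")
        scores = []
        for sigma in (0.0, 0.01, 0.03):
            rng = np.random.default_rng(9)
            sites = np.mod(p4_scatterers.sites +
                           rng.normal(0, sigma, p4_scatterers.sites.shape), 1)
            fs = calc_structure_factors(ScattererModel(p4_scatterers.cell, sites), 3.5)
            scores.append(r_symop(fs, op)[0])
        assert scores[0] < scores[1] < scores[2]

    def test_no_pairs_error(self):
        # every reflection on the fourfold axis is self-paired
        rs = ReflectionSet(UnitCell(20, 20, 20), SpaceGroupDef.from_symbol("P1"),
                           [(0, 0, 1), (0, 0, 2)], [1.0, 2.0])
        with pytest.raises(NoPairsError):
            r_symop(rs, Op.from_triplet("-y,x,z"))


class TestScorePattersonSettings:
    def test_perfect_p4_keeps_tetragonal_setting_only(self, p4_scatterers):
        cell = p4_scatterers.cell
        settings = enumerate_patterson_settings(
            cell, find_lattice_twofolds(cell, 1.4), 8
        )
        fs = calc_structure_factors(p4_scatterers, 3.5)
        scored = score_patterson_settings(fs, settings, r_max=0.25)
        by_symbol = {s.patterson_symbol: s for s in scored}
        assert by_symbol["P4/m"].plausible
        assert by_symbol["P4/m"].max_rsymop_calc <= 1e-12
        assert by_symbol["P-1"].plausible  # trivial setting always survives
        # the in-plane twofolds of 4/mmm are not satisfied by the model
        assert not by_symbol["P4/mmm"].plausible
        assert by_symbol["P4/mmm"].max_rsymop_calc > 0.25
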