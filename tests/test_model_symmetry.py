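"""Superposition, chain matching, origin refinement, ASU models."""

import numpy as np
import pytest

from symcheck.model import Chain, CrystalModel
from symcheck.model_symmetry import (
    MatchError,
    build_asu_models,
    kearsley_superpose,
    match_chains,
    refine_origin,
    residual_deviations,
)
from symcheck.symmetry_core import SpaceGroupDef, left_cosets
from symcheck.synthetic import make_underassigned_structure


def _svd_superpose(A, B):
    """Independent Kabsch/SVD reference implementation."""
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1, 1, d]) @ U.T
    t = ca - cb @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((A - (B @ R.T + t)) ** 2, axis=1))))
    return R, t, rmsd


class TestKearsley:
    def test_identical_sets_give_identity(self):
        A = np.random.default_rng(0).random((10, 3)) * 20
        R, t, rmsd = kearsley_superpose(A, A)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0, atol=1e-9)
        assert rmsd <= 1e-9

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        B = rng.random((12, 3)) * 15
        th = 0.7
        R0 = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0],
                       [0, 0, 1]])
        t0 = np.array([3.0, -1.0, 2.5])
        A = B @ R0.T + t0
        R, t, rmsd = kearsley_superpose(A, B)
        assert np.allclose(R, R0, atol=1e-10)
        assert np.allclose(t, t0, atol=1e-9)
        assert rmsd <= 1e-10
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle_with_noise(self):
        rng = np.random.default_rng(2)
        B = rng.random((30, 3)) * 25
        R0, _, _ = kearsley_superpose(rng.random((4, 3)), rng.random(
            (4, 3)))  # just some proper rotation
        A = B @ R0.T + rng.normal(0, 0.3, B.shape)
        Rk, tk, rk = kearsley_superpose(A, B)
        Rs, ts, rs = _svd_superpose(A, B)
        assert np.allclose(Rk, Rs, atol=1e-8)
        assert np.allclose(tk, ts, atol=1e-8)
        assert rk == pytest.approx(rs, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kearsley_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


@pytest.fixture(scope="module")
def p4_match_setup(request):
    model, truth = make_underassigned_structure(
        "P4", chains_per_asu=2, subgroup="P1", seed=5
    )
    G = SpaceGroupDef.from_symbol("P4")
    cosets = left_cosets(G, model.group)
    return model, G, cosets


class TestMatchChains:
    def test_perfect_fixture_matches_bijectively(self, p4_match_setup):
        model, G, cosets = p4_match_setup
        matches = match_chains(model, model.group, cosets, np.zeros(3))
        # 3 nontrivial representatives x 8 chains
        assert len(matches) == 3 * model.n_chains
        for rep in cosets.representatives:
            sub = [m for m in matches if m.coset_rep == rep]
            assert len({m.source_chain for m in sub}) == model.n_chains
            assert len({m.target_chain for m in sub}) == model.n_chains
        assert all(m.rmsd <= 1e-9 for m in matches)

    def test_displaced_chain_raises_match_error(self, p4_match_setup):
        model, G, cosets = p4_match_setup
        chains = [Chain(c.chain_id, c.seq, c.frac.copy()) for c in model.chains]
        chains[3].frac = chains[3].frac + np.array([0.17, 0.05, 0.31])
        broken = CrystalModel(model.cell, model.group, chains)
        with pytest.raises(MatchError):
            match_chains(broken, broken.group, cosets, np.zeros(3))

    def test_tolerance_gates_noisy_matches(self):
        model, _ = make_underassigned_structure(
            "P4", chains_per_asu=2, subgroup="P1", seed=5, noise_sigma=0.05,
        )
        cosets = left_cosets(SpaceGroupDef.from_symbol("P4"), model.group)
        with pytest.raises(MatchError):
            match_chains(model, model.group, cosets, np.zeros(3), tol=1e-6)


class TestRefineOrigin:
    def test_recovers_applied_shift_exactly(self):
        shift = (0.11, 0.23, 0.0)
        model, truth = make_underassigned_structure(
            "P4", chains_per_asu=2, subgroup="P1", seed=5, origin_shift=shift,
        )
        G = SpaceGroupDef.from_symbol("P4")
        cosets = left_cosets(G, model.group)
        x0 = -np.asarray(shift)
        matches = match_chains(model, model.group, cosets, x0)
        res = refine_origin(matches, model, cosets, x0)
        # x + shift must lie on the allowed-origin lattice of P4
        # (halves along a, b); z is polar and pinned to 0
        d = np.mod(res.x_refined[:2] + shift[:2], 0.5)
        assert np.all(np.minimum(d, 0.5 - d) < 1e-10)
        assert res.x_refined[2] == pytest.approx(0.0, abs=1e-10)
        assert res.delta_r_sym <= 1e-9

    def test_delta_r_sym_identity(self):
        model, truth = make_underassigned_structure(
            "P4", chains_per_asu=2, subgroup="P1", seed=7, noise_sigma=0.03,
        )
        G = SpaceGroupDef.from_symbol("P4")
        cosets = left_cosets(G, model.group)
        matches = match_chains(model, model.group, cosets, np.zeros(3))
        res = refine_origin(matches, model, cosets)
        assert res.delta_r_sym == pytest.approx(
            np.sqrt(res.f_min / res.total_matches), rel=1e-12
        )

    def test_noise_scaling_of_delta_r_sym(self):
        # independent N(0, sigma) per cartesian coordinate on both members
        # of each matched pair: E[dr_sym^2] = 6 sigma^2 (difference of two
        # 3D gaussians), so dr_sym ~ sqrt(6) sigma
        sigma = 0.04
        vals = []
        for seed in (11, 12, 13):
            model, _ = make_underassigned_structure(
                "P4", chains_per_asu=2, subgroup="P1", seed=seed,
                noise_sigma=sigma,
            )
            G = SpaceGroupDef.from_symbol("P4")
            cosets = left_cosets(G, model.group)
            matches = match_chains(model, model.group, cosets, np.zeros(3))
            vals.append(refine_origin(matches, model, cosets).delta_r_sym)
        assert np.mean(vals) == pytest.approx(np.sqrt(6) * sigma, rel=0.15)


class TestASUModels:
    def _pipeline_pieces(self, **kwargs):
        model, truth = make_underassigned_structure(
            "P4", chains_per_asu=2, subgroup="P1", **kwargs
        )
        G = SpaceGroupDef.from_symbol("P4")
        cosets = left_cosets(G, model.group)
        matches = match_chains(model, model.group, cosets, np.zeros(3))
        res = refine_origin(matches, model, cosets)
        asu = build_asu_models(model, matches, cosets, res.x_refined)
        return model, asu, res

    def test_perfect_fixture_gives_identical_models(self):
        model, asu, res = self._pipeline_pieces(seed=5)
        assert asu.n_models == 4
        ref = asu.models[0].all_frac()
        for m in asu.models[1:]:
            assert np.allclose(m.all_frac(), ref, atol=1e-9)
        # each ASU model holds one quarter of the presented chains
        assert all(m.n_chains == 2 for m in asu.models)

    def test_primary_model_keeps_first_in_file_chains(self):
        model, asu, res = self._pipeline_pieces(seed=5)
        first_two = [ch.chain_id for ch in model.chains[:2]]
        assert [ch.chain_id for ch in asu.models[0].chains] == first_two

    def test_per_atom_noise_gives_comparable_deviations(self):
        model, asu, res = self._pipeline_pieces(seed=9, noise_sigma=0.04)
        dr_asu, dr_chain = residual_deviations(asu)
        # per-atom scatter is not absorbed by rigid superposition:
        # all three deviations should be of the same order
        assert dr_asu == pytest.approx(res.delta_r_sym, rel=0.25)
        assert dr_chain == pytest.approx(res.delta_r_sym, rel=0.25)

    def test_rigid_perturbation_is_absorbed_by_superposition(self):
        model, asu, res = self._pipeline_pieces(
            seed=9, rigid_rot_deg=2.0, rigid_shift=0.01
        )
        dr_asu, dr_chain = residual_deviations(asu)
        # whole-body motion inflates dr_sym but vanishes after per-chain
        # superposition
        assert res.delta_r_sym > 5 * max(dr_chain, 1e-6)
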