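"""Synthetic underassigned-symmetry crystals with known ground truth.

The generator builds a toy protein crystal in a chosen Sohncke space
group, then deliberately presents it in a subgroup setting: the ASU
chains are expanded by the coset representatives, per-atom Gaussian
coordinate noise emulates experimental uncertainty, and an origin shift
plus (optionally) a random unimodular change of basis scramble the
frame.  Every stage of the detection pipeline can then be validated
against the recorded ground truth.

Chains are C-alpha traces from a self-avoiding random walk with the
canonical 3.8 A consecutive spacing -- no secondary structure or side
chains, which none of the scored statistics depend on.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, asdict
from fractions import Fraction

import numpy as np

from .intensities import ReflectionSet, calc_structure_factors, merge_under_group
from .lattice_symmetry import UnitCell
from .model import Chain, CrystalModel
from .symmetry_core import (
    ChangeOfBasisOp,
    RationalSymOp,
    SpaceGroupDef,
    left_cosets,
)

__all__ = [
    "GroundTruth",
    "make_chain",
    "make_underassigned_structure",
    "simulate_observed_intensities",
]

CA_STEP = 3.8          # consecutive C-alpha spacing, Angstrom
MIN_SEPARATION = 4.0   # non-consecutive C-alpha clash distance, Angstrom
MIN_CONTACT = 3.0      # inter-chain / symmetry-copy clash distance, Angstrom

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GroundTruth:
    true_group: str
    presented_group: str
    applied_cb: str               # xyz triplet of the basis scramble
    applied_origin_shift: tuple[float, float, float]
    noise_sigma: float            # A per cartesian coordinate
    seed: int
    chains_per_asu: int
    n_chains_presented: int
    n_cosets: int
    cell: tuple[float, ...]

    def to_dict(self) -> dict:
        return asdict(self)


def make_chain(n_res: int, seed: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Self-avoiding C-alpha walk: 3.8 A steps, >= 4.0 A non-consecutive
    separation.  Deterministic per seed; raises after bounded retries."""
    if n_res < 5:
        raise ValueError("need at least 5 residues")
    rng = rng if rng is not None else np.random.default_rng(seed)
    for _attempt in range(50):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n_res - 1):
            placed = False
            for _try in range(200):
                v = rng.normal(size=3)
                v *= CA_STEP / np.linalg.norm(v)
                cand = pts[-1] + v
                prev = np.array(pts[:-1]) if len(pts) > 1 else None
                if prev is None or np.min(
                    np.linalg.norm(prev - cand, axis=1)
                ) >= MIN_SEPARATION:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("chain placement failed after bounded retries")


def _default_cell(group: SpaceGroupDef, rng: np.random.Generator) -> UnitCell:
    """A cell with exactly the group's metric symmetry, nothing more.

    A generic seed metric is averaged over the group's rotation parts
    (G -> mean of W^T G W), which enforces precisely the isometries the
    group requires while keeping the free parameters generic.
    """
    seed = UnitCell(42.0, 49.0, 55.0, 95.0, 99.0, 107.0)
    G = seed.metric
    rots = [RationalSymOp(W).rot_array() for W in group.rotation_parts()]
    G_sym = sum(W.T @ G @ W for W in rots) / len(rots)
    return UnitCell.from_metric(G_sym)


def _min_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.min(np.sum(d * d, axis=-1))))


def _all_copies(frac: np.ndarray, group: SpaceGroupDef, cell: UnitCell) -> list[np.ndarray]:
    """Cartesian coordinates of every symmetry copy in a 3^3 cell block."""
    out = []
    for op in group.operators:
        base = op.apply(frac)
        for shift in np.ndindex(3, 3, 3):
            sh = np.array(shift) - 1
            out.append(cell.orthogonalize(base + sh))
    return out


def make_underassigned_structure(
    true_group: str,
    chains_per_asu: int = 2,
    noise_sigma: float = 0.0,
    origin_shift=(0.0, 0.0, 0.0),
    subgroup: str = "P1",
    cb_scramble: bool = False,
    seed: int = 0,
    n_res: int = 15,
    cell: UnitCell | None = None,
    rigid_rot_deg: float = 0.0,
    rigid_shift: float = 0.0,
) -> tuple[CrystalModel, GroundTruth]:
    """Build a crystal in *true_group* and present it in *subgroup*.

    The returned model carries the subgroup's symmetry and one subgroup
    ASU of chains (true-group ASU expanded by the coset
    representatives), with independent isotropic Gaussian noise of
    *noise_sigma* A per cartesian coordinate, shifted by *origin_shift*
    (fractional) and optionally re-expressed in a random unimodular
    basis (only for P1 presentations, where the symbol stays valid).
    """
    rng = np.random.default_rng(seed)
    G = SpaceGroupDef.from_symbol(true_group)
    H = SpaceGroupDef.from_symbol(subgroup)
    cosets = left_cosets(G, H)
    cell = cell or _default_cell(G, rng)

    # build and place the true-group ASU chains without clashes
    placed_frac: list[np.ndarray] = []
    placed_copies: list[np.ndarray] = []
    for k in range(chains_per_asu):
        chain_cart = make_chain(n_res, seed, rng=rng)
        ok = False
        for _try in range(400):
            centroid = rng.uniform(0.12, 0.42, size=3)
            frac = cell.fractionalize(chain_cart - chain_cart.mean(axis=0)) + centroid
            copies = _all_copies(frac, G, cell)
            cart = cell.orthogonalize(frac)
            clash = False
            for cp in copies:
                dmin = _min_cross_distance(cart, cp)
                if 1e-6 < dmin < MIN_CONTACT:
                    clash = True
                    break
            if not clash:
                for other in placed_copies:
                    if _min_cross_distance(cart, other) < MIN_CONTACT:
                        clash = True
                        break
            if not clash:
                placed_frac.append(frac)
                placed_copies.extend(copies)
                ok = True
                break
        if not ok:
            raise RuntimeError("could not place chains without clashes: cell too small")

    # expand the true-group ASU into the subgroup ASU
    ids = iter(string.ascii_uppercase + string.ascii_lowercase + string.digits)
    seqs = ["".join(rng.choice(list(_AA), size=n_res)) for _ in range(chains_per_asu)]
    chains: list[Chain] = []
    for rep in cosets.all_representatives():
        for frac, seq in zip(placed_frac, seqs):
            chains.append(Chain(next(ids), seq, rep.apply(frac)))

    # per-atom noise and/or per-chain rigid perturbation (cartesian),
    # origin shift, optional basis scramble.  The rigid mode creates
    # true-pseudosymmetry negatives: chains move as bodies, so the
    # deviation from symmetry is not absorbed by per-atom scatter.
    for ch in chains:
        if noise_sigma > 0:
            noise = rng.normal(0.0, noise_sigma, size=ch.frac.shape)
            ch.frac = ch.frac + cell.fractionalize(noise)
        if rigid_rot_deg > 0 or rigid_shift > 0:
            cart = cell.orthogonalize(ch.frac)
            ctr = cart.mean(axis=0)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = np.radians(rng.uniform(-rigid_rot_deg, rigid_rot_deg))
            Kx = np.array([[0, -axis[2], axis[1]],
                           [axis[2], 0, -axis[0]],
                           [-axis[1], axis[0], 0]])
            R = np.eye(3) + np.sin(ang) * Kx + (1 - np.cos(ang)) * (Kx @ Kx)
            dt = rng.uniform(-rigid_shift, rigid_shift, size=3)
            ch.frac = cell.fractionalize((cart - ctr) @ R.T + ctr + dt)
    shift = _sanitize_shift(np.asarray(origin_shift, dtype=float), H)
    model = CrystalModel(cell, H, chains, source="synthetic")
    model = model.shifted(shift)
    cb = ChangeOfBasisOp.identity()
    if cb_scramble:
        if H.order > 1:
            raise ValueError("basis scramble is only supported for P1 presentations")
        cb = random_unimodular_cb(rng)
        model = model.change_basis(cb)
    truth = GroundTruth(
        true_group=G.symbol,
        presented_group=H.symbol,
        applied_cb=cb.triplet(),
        applied_origin_shift=tuple(float(v) for v in shift),
        noise_sigma=noise_sigma,
        seed=seed,
        chains_per_asu=chains_per_asu,
        n_chains_presented=len(chains),
        n_cosets=cosets.n_cosets,
        cell=model.cell.parameters,
    )
    return model, truth


def _sanitize_shift(shift: np.ndarray, H: SpaceGroupDef) -> np.ndarray:
    """Restrict the shift so the presented group's operators stay at
    their conventional positions (shifts must be allowed origins of H)."""
    if H.order == 1:
        return shift
    out = shift.copy()
    eye = np.eye(3)
    for i in range(3):
        polar = all(
            np.array_equal(RationalSymOp(W).rot_array() @ eye[:, i], eye[:, i])
            for W in H.rotation_parts()
        )
        if not polar:
            out[i] = round(2.0 * out[i]) / 2.0
    return out


def random_unimodular_cb(rng: np.random.Generator, n_shears: int = 3) -> ChangeOfBasisOp:
    """Random integer matrix with determinant +1 and small entries."""
    M = np.eye(3, dtype=int)
    for _ in range(n_shears):
        i, j = rng.choice(3, size=2, replace=False)
        S = np.eye(3, dtype=int)
        S[i, j] = int(rng.integers(-1, 2))
        M = M @ S
        perm = rng.permutation(3)
        P = np.eye(3, dtype=int)[perm]
        if np.linalg.det(P) < 0:
            P[[0, 1]] = P[[1, 0]]
        M = M @ P
    Mfrac = tuple(tuple(Fraction(int(v)) for v in row) for row in M)
    return ChangeOfBasisOp(Mfrac)


def simulate_observed_intensities(
    model: CrystalModel,
    d_min: float = 3.5,
    frac_noise: float = 0.0,
    completeness: float = 1.0,
    seed: int = 0,
) -> ReflectionSet:
    """Emulate a merged observed data set for the presented model.

    Calculated intensities (P1 expansion of the model) are merged in the
    presented group, perturbed with multiplicative Gaussian noise of
    coefficient of variation *frac_noise*, and subsampled to the stated
    completeness.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p1 = model.expand_to_p1()
    fs = calc_structure_factors(p1.to_scatterers(), d_min)
    merged = merge_under_group(fs, model.group)
    I = merged.I.copy()
    if frac_noise > 0:
        I = np.clip(I * (1.0 + rng.normal(0.0, frac_noise, size=len(I))), 0.0, None)
    keep = np.arange(len(I))
    if completeness < 1.0:
        keep = np.sort(rng.choice(len(I), size=int(round(completeness * len(I))),
                                  replace=False))
    sig = np.maximum(frac_noise * I[keep], 1e-6)
    return ReflectionSet(model.cell, model.group, merged.hkl[keep], I[keep], sigI=sig)
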