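"""Model positioning and rotation/screw discrimination.

Two reciprocal-space scores locate a model in a candidate space group G:

* the intensity correlation r(x, G) between I_merge (the model's P1
  intensities merged under G) and I_ensemble(x) (intensities of the
  superposition of all G-copies of the model shifted by x), evaluated on
  a fractional grid -- peaks near 1 mark candidate origin shifts;
* the amplitude-weighted phase-agreement score Phi(g) which is zero for
  a model exactly invariant under g and grows toward ~0.5 for a
  mismatched (e.g. screw-instead-of-rotation) operator.  Intensities
  cannot tell a rotation from its screw counterpart; phases can.

The map is evaluated by accumulating the pair/quadruple interference
terms of the ensemble intensity on the reciprocal grid and inverse-FFT;
this is algebraically identical to direct per-gridpoint evaluation (the
correctness reference used in the tests) up to rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .intensities import (
    ReflectionSet,
    calc_structure_factors,
    friedel_canonical,
    hemisphere_indices,
    merge_under_group,
)
from .lattice_symmetry import PattersonSetting, UnitCell
from .model import ScattererModel
from .symmetry_core import (
    CosetDecomposition,
    RationalSymOp,
    SpaceGroupDef,
    candidate_space_groups,
    left_cosets,
)

__all__ = [
    "CorrelationMap",
    "PhaseScoreConfig",
    "SpaceGroupCandidate",
    "correlation_map",
    "phase_agreement",
    "rank_space_groups",
]

# budget for the quartic interference accumulation; reflections are
# subsampled (strongest first) beyond it
_MAX_QUARTIC_TERMS = 40_000_000


@dataclass
class PhaseScoreConfig:
    """Normalization of the phase-agreement score.

    Weights are squared amplitudes; phase differences are wrapped into
    (-pi/n, pi/n] and normalized by C = (pi/n) sum |F|^2 so the score
    lies in [0, 1] and is exactly 0 for an invariant model.
    """

    modular_order: int = 1


@dataclass
class CorrelationMap:
    group: SpaceGroupDef
    grid_divisions: tuple[int, int, int]
    values: np.ndarray           # (N1, N2, N3), Pearson r per grid point
    x_max: np.ndarray            # fractional triple, polar components zeroed
    r_max: float
    n_reflections: int


def _polar_axes(G: SpaceGroupDef) -> list[int]:
    """Cell axes along which every rotation part acts as identity."""
    out = []
    eye = np.eye(3)
    for i in range(3):
        if all(
            np.array_equal(RationalSymOp(W).rot_array() @ eye[:, i], eye[:, i])
            for W in G.rotation_parts()
        ):
            out.append(i)
    return out


def _grid_for(cell: UnitCell, d_min: float) -> tuple[int, int, int]:
    return tuple(
        max(2, int(math.ceil(length / (0.5 * d_min))))
        for length in (cell.a, cell.b, cell.c)
    )


def _sf_lookup(fs: ReflectionSet, K: np.ndarray) -> np.ndarray:
    """F at arbitrary (possibly Friedel-flipped) integer indices."""
    canon = friedel_canonical(K)
    flipped = np.any(canon != K, axis=1)
    idx, found = fs.lookup(canon)
    if not np.all(found):
        raise KeyError("index outside calculated reflection set")
    F = fs.F[idx].copy()
    F[flipped] = np.conj(F[flipped])
    return F


def correlation_map(
    model_p1: ScattererModel,
    G: SpaceGroupDef,
    d_min: float,
    grid_divisions: tuple[int, int, int] | None = None,
    config: PhaseScoreConfig | None = None,
) -> CorrelationMap:
    """Pearson correlation r(x, G) on a fractional grid.

    For each grid point x, r is the correlation over Miller indices
    between the model's P1 intensities merged under G and the intensities
    of the ensemble of all G-copies of the model shifted by x.
    """
    cell = model_p1.cell
    N = grid_divisions or _grid_for(cell, d_min)
    fs = calc_structure_factors(model_p1, d_min)
    if fs.n_reflections < 10:
        raise ValueError("fewer than 10 reflections: correlation is meaningless")
    H = fs.hkl
    ops = G.operators
    n_ops = len(ops)

    # merged intensities, broadcast back per reflection
    merged = merge_under_group(fs, G)
    rep = _orbit_reps(fs, G)
    midx, mfound = merged.lookup(rep)
    assert np.all(mfound)
    I_m = merged.I[midx]

    # subsample strongest reflections if the quartic accumulation would
    # be too large
    n_keep = len(H)
    budget = _MAX_QUARTIC_TERMS // max(1, n_ops ** 4)
    if n_keep > budget:
        order = np.argsort(I_m)[::-1][:budget]
        order.sort()
        H, I_m = H[order], I_m[order]
    nH = len(H)

    # per-operator phased structure factors A_g(H) and mapped indices K_g
    K_list, A_list = [], []
    for g in ops:
        K = g.apply_to_miller(H)
        phase = np.exp(2j * np.pi * (H @ g.tran_array()))
        K_list.append(K)
        A_list.append(phase * _sf_lookup(fs, K))
    K_arr = np.stack(K_list)            # (n_ops, nH, 3)
    A_arr = np.stack(A_list)            # (n_ops, nH)

    Ngrid = np.array(N)
    S_xy = _interference_field(K_arr, A_arr, N, weights=I_m, power=2)
    S_1 = _interference_field(K_arr, A_arr, N, weights=None, power=2)
    S_2 = _interference_field(K_arr, A_arr, N, weights=None, power=4)

    mx = I_m.mean()
    vx = I_m.var()
    my = S_1 / nH
    vy = np.maximum(S_2 / nH - my ** 2, 0.0)
    cov = S_xy / nH - mx * my
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.maximum(denom, 1e-300), 0.0)

    flat = np.round(r.ravel(), 9)
    imax = int(np.argmax(flat))
    i1, i2, i3 = np.unravel_index(imax, N)
    x_max = np.array([i1 / N[0], i2 / N[1], i3 / N[2]])
    polar = _polar_axes(G)
    for ax in polar:
        x_max[ax] = 0.0
    # polish the peak off-grid (the grid only resolves ~d_min/2)
    x_max, r_peak = _polish_peak(K_arr, A_arr, I_m, x_max, polar)
    for ax in polar:
        x_max[ax] = 0.0
    return CorrelationMap(G, tuple(N), r, x_max, r_peak, nH)


def _correlation_at(K_arr, A_arr, I_m, x) -> float:
    """Direct evaluation of r(x, G) at a single fractional position."""
    phase = np.exp(2j * np.pi * np.einsum("ghk,k->gh", K_arr.astype(float), x))
    S = np.sum(A_arr * phase, axis=0)
    I_e = np.abs(S) ** 2
    vi, ve = I_m.var(), I_e.var()
    if vi <= 0 or ve <= 0:
        return 0.0
    return float(np.mean((I_m - I_m.mean()) * (I_e - I_e.mean())) / np.sqrt(vi * ve))


def _polish_peak(K_arr, A_arr, I_m, x0, polar) -> tuple[np.ndarray, float]:
    from scipy.optimize import minimize

    free = [i for i in range(3) if i not in polar]
    if not free:
        return x0, _correlation_at(K_arr, A_arr, I_m, x0)

    def neg(v):
        x = x0.copy()
        x[free] = v
        return -_correlation_at(K_arr, A_arr, I_m, x)

    res = minimize(neg, x0[free], method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 400})
    x = x0.copy()
    x[free] = np.mod(res.x, 1.0)
    return x, float(-res.fun)


def _orbit_reps(fs: ReflectionSet, G: SpaceGroupDef) -> np.ndarray:
    """Lexicographically-smallest orbit member per reflection (Friedel incl.)."""
    rep = fs.hkl.copy()
    for W in G.rotation_parts():
        mapped = friedel_canonical(RationalSymOp(W).apply_to_miller(fs.hkl))
        from .intensities import _lex_less

        smaller = _lex_less(mapped, rep)
        rep[smaller] = mapped[smaller]
    return rep


def _interference_field(K_arr, A_arr, N, weights, power) -> np.ndarray:
    """Accumulate sum_H w_H |S_H(x)|^power on the grid via inverse FFT.

    S_H(x) = sum_g A_g(H) exp(2 pi i K_g(H) . x); power is 2 or 4.
    """
    n_ops, nH, _ = K_arr.shape
    C = np.zeros(tuple(N), dtype=complex)
    Nv = np.array(N)
    w = np.ones(nH) if weights is None else weights
    pairs = [(g1, g2) for g1 in range(n_ops) for g2 in range(n_ops)]
    if power == 2:
        for g1, g2 in pairs:
            D = np.mod(K_arr[g1] - K_arr[g2], Nv)
            c = w * A_arr[g1] * np.conj(A_arr[g2])
            np.add.at(C, (D[:, 0], D[:, 1], D[:, 2]), c)
    elif power == 4:
        for g1, g2 in pairs:
            D12 = K_arr[g1] - K_arr[g2]
            c12 = A_arr[g1] * np.conj(A_arr[g2])
            for g3, g4 in pairs:
                D = np.mod(D12 + K_arr[g3] - K_arr[g4], Nv)
                c = w * c12 * A_arr[g3] * np.conj(A_arr[g4])
                np.add.at(C, (D[:, 0], D[:, 1], D[:, 2]), c)
    else:
        raise ValueError(power)
    field = np.fft.ifftn(C) * np.prod(Nv)
    return np.real(field)


def phase_agreement(
    model_p1_shifted: ScattererModel,
    g: RationalSymOp,
    d_min: float,
    config: PhaseScoreConfig | None = None,
    reflections: ReflectionSet | None = None,
) -> float:
    """Amplitude-weighted phase-mismatch score Phi(g) in [0, 1].

    Phi = sum_H |F_H|^2 |wrap(phi_H - phi_HW - 2 pi H.w)| / C with
    C = (pi/n) sum_H |F_H|^2; exactly 0 for an invariant model.
    """
    config = config or PhaseScoreConfig()
    n = config.modular_order
    fs = reflections if reflections is not None else calc_structure_factors(
        model_p1_shifted, d_min
    )
    if fs.n_reflections == 0:
        raise ValueError("empty reflection set")
    F = fs.F
    K = g.apply_to_miller(fs.hkl)
    FK = _sf_lookup(fs, K)
    dphi = np.angle(F) - np.angle(FK) - 2.0 * np.pi * (fs.hkl @ g.tran_array())
    period = 2.0 * np.pi / n
    wrapped = dphi - period * np.round(dphi / period)
    w = np.abs(F) ** 2
    C = (np.pi / n) * np.sum(w)
    if C == 0:
        raise ValueError("all amplitudes are zero")
    return float(np.sum(w * np.abs(wrapped)) / C)


@dataclass
class SpaceGroupCandidate:
    group: SpaceGroupDef
    x_max: np.ndarray
    r_max: float
    phi_max: float | None
    phi_by_rep: dict[str, float] = field(default_factory=dict)
    cosets: CosetDecomposition | None = None
    dropped_reason: str | None = None

    @property
    def retained(self) -> bool:
        return self.dropped_reason is None


def conjugate_by_shift(H: SpaceGroupDef, x: np.ndarray) -> SpaceGroupDef:
    """Input-group operators in the origin-shifted frame (x snapped to /24).

    Shifting the model by x turns an invariance operator (W, w) into
    (W, w + (I - W) x); the snap keeps the algebra exact (origin shifts
    relating space-group settings have denominators dividing 24).
    """
    from fractions import Fraction

    xs = tuple(Fraction(int(round(float(v) * 24)), 24) for v in x)
    ops = []
    for h in H.operators:
        shift = tuple(
            xs[i] - sum(h.W[i][j] * xs[j] for j in range(3)) for i in range(3)
        )
        ops.append(RationalSymOp(h.W, tuple(a + b for a, b in zip(h.w, shift))))
    return SpaceGroupDef(H.symbol, tuple(ops), H.sohncke, H.patterson_symbol,
                         H.crystal_system, H.number, H.hall)


def rank_space_groups(
    model_p1: ScattererModel,
    patterson: PattersonSetting,
    d_min: float,
    input_group: SpaceGroupDef | None = None,
    r_min: float = 0.8,
    config: PhaseScoreConfig | None = None,
) -> list[SpaceGroupCandidate]:
    """Rank the candidate space groups of a Patterson setting.

    For each Sohncke group sharing the setting's Patterson symmetry:
    locate the model via the correlation map, then score every coset
    representative of G over the input group with Phi.  Groups whose
    correlation peak falls below *r_min* cannot win the ranking and carry
    a reason code.  Ranking: max Phi ascending, then r_max descending.
    """
    if input_group is None:
        input_group = SpaceGroupDef.from_symbol("P1")
    out = []
    for G in candidate_space_groups(patterson.patterson_symbol):
        cmap = correlation_map(model_p1, G, d_min, config=config)
        shifted = model_p1.shifted(cmap.x_max)
        fs = calc_structure_factors(shifted, d_min)
        reason = None
        cosets = None
        phi_by_rep: dict[str, float] = {}
        try:
            Hconj = conjugate_by_shift(input_group, cmap.x_max)
            cosets = left_cosets(G, Hconj)
        except ValueError as exc:
            reason = f"input group is not a subgroup at the peak shift: {exc}"
        if cosets is not None:
            for repop in cosets.representatives:
                phi_by_rep[repop.triplet()] = phase_agreement(
                    shifted, repop, d_min, config=config, reflections=fs
                )
        phi_max = max(phi_by_rep.values()) if phi_by_rep else None
        if reason is None and cmap.r_max < r_min:
            reason = f"correlation peak {cmap.r_max:.3f} below threshold {r_min:.2f}"
        out.append(SpaceGroupCandidate(
            G, cmap.x_max, cmap.r_max, phi_max, phi_by_rep, cosets, reason,
        ))
    retained = [c for c in out if c.retained]
    dropped = [c for c in out if not c.retained]
    key = lambda c: (c.phi_max if c.phi_max is not None else 2.0, -c.r_max)
    retained.sort(key=key)
    dropped.sort(key=key)
    return retained + dropped
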