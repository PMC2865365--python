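"""Coordinate-space symmetry verdict.

Given a candidate supergroup G of the model's group H, the questions are:
which chains map onto which under each trial operator (one left-coset
representative per coset of H in G), what origin shift best aligns those
matches, and how large is the residual deviation from perfect symmetry.

The deviation is summarized by three RMS quantities over matched C-alpha
pairs: dr_sym (raw deviation from symmetry-predicted positions after
origin refinement), dr_asu (after a rigid-body superposition of whole
ASU models, isolating per-atom scatter from rigid motion) and dr_chain
(likewise with per-chain superpositions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model import Chain, CrystalModel
from .symmetry_core import CosetDecomposition, RationalSymOp, SpaceGroupDef

__all__ = [
    "ChainMatch",
    "MatchError",
    "OriginRefinementResult",
    "ASUModelSet",
    "SymmetryReport",
    "kearsley_superpose",
    "match_chains",
    "refine_origin",
    "build_asu_models",
    "residual_deviations",
]


class MatchError(ValueError):
    """Chain matching failed (unmatched or ambiguous assignments)."""


def kearsley_superpose(
    A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of B onto A (quaternion method).

    Solves the 4x4 eigenproblem of Kearsley (1989); the smallest
    eigenvalue is the residual sum of squares, so rmsd = sqrt(l_min/N).
    Returns (rotation, translation, rmsd) with ``A ~ B @ R.T + t`` and
    det(R) = +1.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("point sets must have equal shapes")
    if len(A) < 3:
        raise ValueError("need at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    m = (A - ca) - (B - cb)   # differences
    p = (A - ca) + (B - cb)   # sums
    xm, ym, zm = m.T
    xp, yp, zp = p.T
    K = np.empty((4, 4))
    K[0, 0] = np.sum(xm * xm + ym * ym + zm * zm)
    K[0, 1] = K[1, 0] = np.sum(yp * zm - ym * zp)
    K[0, 2] = K[2, 0] = np.sum(xm * zp - xp * zm)
    K[0, 3] = K[3, 0] = np.sum(xp * ym - xm * yp)
    K[1, 1] = np.sum(yp * yp + zp * zp + xm * xm)
    K[1, 2] = K[2, 1] = np.sum(xm * ym - xp * yp)
    K[1, 3] = K[3, 1] = np.sum(xm * zm - xp * zp)
    K[2, 2] = np.sum(xp * xp + zp * zp + ym * ym)
    K[2, 3] = K[3, 2] = np.sum(ym * zm - yp * zp)
    K[3, 3] = np.sum(xp * xp + yp * yp + zm * zm)
    evals, evecs = np.linalg.eigh(K)
    lam = max(float(evals[0]), 0.0)
    q1, q2, q3, q4 = evecs[:, 0]
    R = np.array([
        [q1 * q1 + q2 * q2 - q3 * q3 - q4 * q4, 2 * (q2 * q3 + q1 * q4), 2 * (q2 * q4 - q1 * q3)],
        [2 * (q2 * q3 - q1 * q4), q1 * q1 - q2 * q2 + q3 * q3 - q4 * q4, 2 * (q3 * q4 + q1 * q2)],
        [2 * (q2 * q4 + q1 * q3), 2 * (q3 * q4 - q1 * q2), q1 * q1 - q2 * q2 - q3 * q3 + q4 * q4],
    ])
    t = ca - cb @ R.T
    rmsd = float(np.sqrt(lam / len(A)))
    return R, t, rmsd


@dataclass
class ChainMatch:
    """A chain pair (X -> Y) matched under a coset representative g_i.

    ``g_i (X + x) ~ h (Y + x) + t`` with h in the input group H and t an
    integer lattice translation.
    """

    coset_rep: RationalSymOp
    source_chain: str
    target_chain: str
    h: RationalSymOp
    t: tuple[int, int, int]
    n_calpha: int
    rmsd: float


def _seq_similar(a: Chain, b: Chain, min_identity: float = 0.95) -> bool:
    if a.n_calpha != b.n_calpha or len(a.seq) != len(b.seq):
        return False
    if not a.seq:
        return True
    same = sum(1 for x, y in zip(a.seq, b.seq) if x == y)
    return same / len(a.seq) >= min_identity


def match_chains(
    model: CrystalModel,
    H: SpaceGroupDef,
    cosets: CosetDecomposition,
    x: np.ndarray,
    tol: float = 2.0,
) -> list[ChainMatch]:
    """Find the chain bijection induced by each coset representative.

    The model's chains are the asymmetric-unit content in the candidate
    frame; *x* is the (approximate) origin shift.  For each nontrivial
    representative g_i and chain X, the best (Y, h, t) with mean C-alpha
    deviation <= *tol* Angstrom is kept.  Raises :class:`MatchError` if
    any (g_i, X) stays unmatched or a target chain is claimed twice.
    """
    x = np.asarray(x, dtype=float)
    O = model.cell.orth
    matches: list[ChainMatch] = []
    failures: list[str] = []
    neighbor = np.array(list(itertools.product((-1, 0, 1), repeat=3)))
    for rep in cosets.representatives:
        used: dict[str, str] = {}
        for X in model.chains:
            gx = rep.apply(X.frac + x)
            best = None
            for Y in model.chains:
                if not _seq_similar(X, Y):
                    continue
                for h in H.operators:
                    hy = h.apply(Y.frac + x)
                    t0 = np.rint(np.mean(gx - hy, axis=0))
                    for dt in neighbor:
                        diff = gx - hy - (t0 + dt)
                        cart = diff @ O.T
                        rms = float(np.sqrt(np.mean(np.sum(cart ** 2, axis=1))))
                        if rms <= tol and (best is None or rms < best[0]):
                            best = (rms, Y, h, tuple(int(v) for v in t0 + dt))
            if best is None:
                failures.append(f"(g={rep.triplet()}, chain {X.chain_id})")
                continue
            rms, Y, h, t = best
            if Y.chain_id in used:
                raise MatchError(
                    f"chain {Y.chain_id} matched twice under g={rep.triplet()} "
                    f"(by {used[Y.chain_id]} and {X.chain_id}): "
                    "symmetry mapping must be a bijection"
                )
            used[Y.chain_id] = X.chain_id
            matches.append(ChainMatch(
                rep, X.chain_id, Y.chain_id, h, t, X.n_calpha, rms,
            ))
    if failures:
        raise MatchError("unmatched chain/operator pairs: " + ", ".join(failures))
    return matches


@dataclass
class OriginRefinementResult:
    x_refined: np.ndarray
    f_min: float             # Angstrom^2, sum of squared residuals
    total_matches: int       # total C-alpha pairs over all cosets
    delta_r_sym: float       # Angstrom; sqrt(f_min / total_matches)


def refine_origin(
    matches: list[ChainMatch],
    model: CrystalModel,
    cosets: CosetDecomposition,
    x0: np.ndarray | None = None,
) -> OriginRefinementResult:
    """Least-squares refinement of the origin shift from chain matches.

    The objective is the Cartesian square difference between matched
    C-alpha positions, f(x) = sum |O[g_i(X + x) - h(Y + x) - t]|^2 --
    quadratic in x, solved by normal equations.  Null-space (polar)
    components are pinned to 0 via the minimum-norm solution.  The model
    coordinates are the un-shifted candidate-frame positions; *x0* is
    unused in the algebra (the optimum is global) but accepted for
    interface symmetry.
    """
    if not matches:
        raise ValueError("no matches to refine against")
    O = model.cell.orth
    chains = {ch.chain_id: ch for ch in model.chains}
    A = np.zeros((3, 3))
    b = np.zeros(3)
    terms = []
    total = 0
    for mt in matches:
        X = chains[mt.source_chain]
        Y = chains[mt.target_chain]
        Wg = mt.coset_rep.rot_array()
        wg = mt.coset_rep.tran_array()
        Wh = mt.h.rot_array()
        wh = mt.h.tran_array()
        D = O @ (Wg - Wh)                       # (3,3)
        c = (X.frac @ Wg.T + wg - Y.frac @ Wh.T - wh - np.array(mt.t)) @ O.T
        A += len(X.frac) * (D.T @ D)
        b -= D.T @ c.sum(axis=0)
        terms.append((D, c))
        total += len(X.frac)
    x_ref, *_ = np.linalg.lstsq(A, b, rcond=1e-10)
    f_min = 0.0
    for D, c in terms:
        res = c + x_ref @ D.T
        f_min += float(np.sum(res ** 2))
    return OriginRefinementResult(
        x_ref, f_min, total, float(np.sqrt(f_min / total))
    )


@dataclass
class ASUModelSet:
    """n nearly-superimposed models of the higher-symmetry ASU.

    The primary model keeps the first-in-file chain of each mutual-match
    group; each further model is the g_i-matched copy mapped back onto
    the primary frame, so inter-model differences show the
    noncrystallographic variability the extra symmetry would absorb.
    """

    models: list[CrystalModel]
    provenance: list[str]    # coset representative triplet per model

    @property
    def n_models(self) -> int:
        return len(self.models)


def build_asu_models(
    model: CrystalModel,
    matches: list[ChainMatch],
    cosets: CosetDecomposition,
    x_refined: np.ndarray,
) -> ASUModelSet:
    """Construct the n ASU models from the mutual chain-match groups."""
    x = np.asarray(x_refined, dtype=float)
    n = cosets.n_cosets
    chains = {ch.chain_id: ch for ch in model.chains}
    order = [ch.chain_id for ch in model.chains]
    # union-find over mutual matches
    parent = {cid: cid for cid in order}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the earlier-in-file chain as root
            if order.index(ra) < order.index(rb):
                parent[rb] = ra
            else:
                parent[ra] = rb

    match_of: dict[tuple[str, str], ChainMatch] = {}
    for mt in matches:
        union(mt.source_chain, mt.target_chain)
        match_of[(mt.coset_rep.triplet(), mt.source_chain)] = mt
    groups: dict[str, list[str]] = {}
    for cid in order:
        groups.setdefault(find(cid), []).append(cid)
    sizes = {len(v) for v in groups.values()}
    if sizes != {n}:
        raise MatchError(
            f"mutual match groups have sizes {sorted(sizes)}, expected {n}"
        )
    primary_ids = [find(cid) for cid in order]
    primary_ids = list(dict.fromkeys(primary_ids))  # first-in-file, stable
    primary = CrystalModel(
        model.cell, model.group,
        [Chain(cid, chains[cid].seq, chains[cid].frac.copy()) for cid in primary_ids],
        model.source,
    )
    models = [primary]
    provenance = ["x,y,z"]
    for rep in cosets.representatives:
        ginv = rep.inverse()
        new_chains = []
        for cid in primary_ids:
            mt = match_of.get((rep.triplet(), cid))
            if mt is None:
                raise MatchError(
                    f"no match for primary chain {cid} under {rep.triplet()}"
                )
            Y = chains[mt.target_chain]
            # map the matched copy back into alignment with the primary:
            # z = g^-1 (h (Y + x) + t) - x
            hy = mt.h.apply(Y.frac + x) + np.array(mt.t)
            z = ginv.apply(hy) - x
            new_chains.append(Chain(Y.chain_id, Y.seq, z))
        models.append(CrystalModel(model.cell, model.group, new_chains, model.source))
        provenance.append(rep.triplet())
    return ASUModelSet(models, provenance)


def residual_deviations(asu: ASUModelSet) -> tuple[float, float]:
    """(dr_asu, dr_chain): residual RMS deviations among ASU models.

    dr_asu superposes the entire C-alpha content of each model pair
    (rigid-body motion of the whole ASU absorbed); dr_chain superposes
    chain pairs individually.  Both are N-weighted RMS over all pairs.
    """
    if asu.n_models < 2:
        raise ValueError("need at least two ASU models")
    cell = asu.models[0].cell
    num_asu = den_asu = 0.0
    num_ch = den_ch = 0.0
    for mi, mj in itertools.combinations(asu.models, 2):
        Ai = cell.orthogonalize(mi.all_frac())
        Aj = cell.orthogonalize(mj.all_frac())
        _, _, rms = kearsley_superpose(Ai, Aj)
        nij = len(Ai)
        num_asu += nij * rms ** 2
        den_asu += nij
        for ci, cj in zip(mi.chains, mj.chains):
            Ci = cell.orthogonalize(ci.frac)
            Cj = cell.orthogonalize(cj.frac)
            _, _, rms_c = kearsley_superpose(Ci, Cj)
            num_ch += len(Ci) * rms_c ** 2
            den_ch += len(Ci)
    return float(np.sqrt(num_asu / den_asu)), float(np.sqrt(num_ch / den_ch))


@dataclass
class SymmetryReport:
    """Verdict for one candidate target group (one Fig. 4 / Table 4 row)."""

    input_group: str
    target_group: str
    patterson_symbol: str
    n_cosets: int
    x_refined: tuple[float, float, float]
    r_max: float
    max_phi: float | None
    delta_r_sym: float
    delta_r_asu: float | None
    delta_r_chain: float | None
    rsymop_calc_max: float
    rsymop_obs_max: float | None
    max_delta_deg: float
    candidate: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "input_group": self.input_group,
            "target_group": self.target_group,
            "patterson_symbol": self.patterson_symbol,
            "n_cosets": self.n_cosets,
            "x_refined": list(self.x_refined),
            "r_max": self.r_max,
            "max_phi": self.max_phi,
            "delta_r_sym": self.delta_r_sym,
            "delta_r_asu": self.delta_r_asu,
            "delta_r_chain": self.delta_r_chain,
            "rsymop_calc_max": self.rsymop_calc_max,
            "rsymop_obs_max": self.rsymop_obs_max,
            "max_delta_deg": self.max_delta_deg,
            "candidate": self.candidate,
            "notes": self.notes,
        }
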