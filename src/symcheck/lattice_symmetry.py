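"""Lattice (metric) symmetry analysis.

Given a unit cell, find every rotational symmetry the *lattice* supports
to within an angular tolerance: reduce the cell (Niggli/Krivy-Gruber),
search for lattice twofolds scored by the Le Page delta angle, close the
accepted twofolds into the full metric rotation group, and enumerate all
Patterson settings (rotation subgroups with their conventional frames)
that a crystal in this cell could belong to.

The delta angle of a candidate axis is the angle between the axis
expressed in direct space (t = u a + v b + w c) and in reciprocal space
(tau = h a* + k b* + l c*); it is zero for an exact lattice symmetry
axis and grows as the metric deviates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import gemmi
import numpy as np

from .symmetry_core import (
    ChangeOfBasisOp,
    RationalSymOp,
    SpaceGroupDef,
    group_closure,
)

__all__ = [
    "UnitCell",
    "LatticeTwofold",
    "PattersonSetting",
    "reduce_cell",
    "remove_centring",
    "find_lattice_twofolds",
    "enumerate_patterson_settings",
]

DEFAULT_DELTA_TOL = 1.4  # degrees; typical rotation-photography misalignment


@dataclass(frozen=True)
class UnitCell:
    """Unit cell; lengths in Angstrom, angles in degrees.

    Orthogonalization follows the PDB convention: a along x, b in the
    xy-plane.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180)")
        if self.volume <= 1e-6 * self.a * self.b * self.c:
            raise ValueError("degenerate cell (volume ~ 0)")

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def metric(self) -> np.ndarray:
        a, b, c = self.a, self.b, self.c
        ca, cb_, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array([
            [a * a, a * b * cg, a * c * cb_],
            [a * b * cg, b * b, b * c * ca],
            [a * c * cb_, b * c * ca, c * c],
        ])

    @property
    def volume(self) -> float:
        det = np.linalg.det(self.metric)
        return math.sqrt(max(det, 0.0))

    @property
    def orth(self) -> np.ndarray:
        """Orthogonalization matrix O: cartesian = O @ fractional."""
        a, b, c = self.a, self.b, self.c
        ca, cb_, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume
        return np.array([
            [a, b * cg, c * cb_],
            [0.0, b * sg, c * (ca - cb_ * cg) / sg],
            [0.0, 0.0, v / (a * b * sg)],
        ])

    @property
    def frac(self) -> np.ndarray:
        return np.linalg.inv(self.orth)

    def orthogonalize(self, frac_coords: np.ndarray) -> np.ndarray:
        return np.asarray(frac_coords) @ self.orth.T

    def fractionalize(self, cart_coords: np.ndarray) -> np.ndarray:
        return np.asarray(cart_coords) @ self.frac.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution of reflections, shape (..., 3) -> (...)."""
        gstar = np.linalg.inv(self.metric)
        h = np.asarray(hkl, dtype=float)
        inv_d2 = np.einsum("...i,ij,...j->...", h, gstar, h)
        return 1.0 / np.sqrt(inv_d2)

    @classmethod
    def from_metric(cls, G: np.ndarray) -> "UnitCell":
        a, b, c = np.sqrt(np.diag(G))
        al = math.degrees(math.acos(G[1, 2] / (b * c)))
        be = math.degrees(math.acos(G[0, 2] / (a * c)))
        ga = math.degrees(math.acos(G[0, 1] / (a * b)))
        return cls(float(a), float(b), float(c), al, be, ga)

    def changed_basis(self, cb: ChangeOfBasisOp) -> "UnitCell":
        return UnitCell.from_metric(cb.apply_to_metric(self.metric))

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.parameters)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


@dataclass(frozen=True)
class LatticeTwofold:
    """A candidate twofold axis of the lattice."""

    uvw: tuple[int, int, int]      # direct-space axis
    hkl: tuple[int, int, int]      # reciprocal-space axis
    delta: float                   # degrees
    operator: RationalSymOp        # integer twofold matrix, this basis


@dataclass
class PattersonSetting:
    """One candidate Patterson symmetry compatible with the cell.

    ``rotational_operators`` are expressed in the (reduced) frame the
    setting was enumerated in; ``cb_from_input`` carries coordinates from
    that frame into the setting's conventional frame, whose (idealized)
    cell is ``conventional_cell``.
    """

    patterson_symbol: str
    cb_from_input: ChangeOfBasisOp
    rotational_operators: tuple[RationalSymOp, ...]
    max_delta: float
    n_chains_in_asu: int
    conventional_cell: UnitCell
    centring: str
    axis_note: str = ""
    max_rsymop_calc: float | None = None
    max_rsymop_obs: float | None = None
    plausible: bool | None = None

    @property
    def rotation_order(self) -> int:
        return len(self.rotational_operators)

    def operator_shorthand(self) -> str:
        return "{" + ", ".join(_op_shorthand(g) for g in self.rotational_operators) + "}"


# ---------------------------------------------------------------------------
# cell reduction and centring removal


def reduce_cell(cell: UnitCell, epsilon: float = 1e-5) -> tuple[UnitCell, ChangeOfBasisOp]:
    """Niggli-reduce a cell; returns (reduced cell, cb input->reduced)."""
    gv = gemmi.GruberVector(cell.to_gemmi(), None, True)
    gv.niggli_reduce(epsilon=epsilon)
    op = gv.change_of_basis
    if op is None:
        return cell, ChangeOfBasisOp.identity()
    # gemmi's Gruber op is a basis-column matrix; coordinates transform by
    # its inverse
    M = tuple(tuple(Fraction(v, gemmi.Op.DEN) for v in row) for row in op.rot)
    cb = ChangeOfBasisOp(M).inverse()
    reduced = cell.changed_basis(cb)
    assert abs(reduced.volume - cell.volume) <= 1e-9 * cell.volume + 1e-9
    return reduced, cb


_CENTRING_BASIS = {
    # columns of the primitive basis in the centred frame (ITC A ch. 5)
    "P": "x,y,z",
    "A": "x,y/2-z/2,y/2+z/2",
    "B": "x/2+z/2,y,-x/2+z/2",
    "C": "x/2+y/2,x/2-y/2,z",
    "I": "-x/2+y/2+z/2,x/2-y/2+z/2,x/2+y/2-z/2",
    "F": "y/2+z/2,x/2+z/2,x/2+y/2",
    "R": "2/3*x-1/3*y-1/3*z,1/3*x+1/3*y-2/3*z,1/3*x+1/3*y+1/3*z",
}


def centring_letter(group: SpaceGroupDef) -> str:
    letter = group.symbol.replace(" ", "")[:1].upper()
    if letter not in _CENTRING_BASIS and letter != "H":
        raise ValueError(f"unknown centring letter {letter!r} in {group.symbol!r}")
    return "R" if letter == "H" else letter


def remove_centring(
    group: SpaceGroupDef, cell: UnitCell
) -> tuple[SpaceGroupDef, UnitCell, ChangeOfBasisOp]:
    """Change basis so that centring translations become lattice vectors.

    Returns (primitive group, primitive cell, cb centred->primitive).
    The cell volume is divided by the centring multiplicity; the operator
    count drops by the same factor.
    """
    letter = centring_letter(group)
    if letter == "P":
        return group, cell, ChangeOfBasisOp.identity()
    basis = ChangeOfBasisOp.from_triplet(_CENTRING_BASIS[letter])
    cb = basis.inverse()  # basis-column matrix -> coordinate map
    prim_ops = {cb.apply_to_op(g) for g in group.operators}
    mult = group.order // len(prim_ops)
    assert mult == round(1 / abs(float(basis.det())))
    prim = SpaceGroupDef(
        group.symbol + " (primitive)", tuple(prim_ops), group.sohncke,
        group.patterson_symbol, group.crystal_system, group.number, group.hall,
    )
    return prim, cell.changed_basis(cb), cb


# ---------------------------------------------------------------------------
# Le Page twofold search


def _coprime_triples(bound: int):
    for u in itertools.product(range(-bound, bound + 1), repeat=3):
        if u == (0, 0, 0):
            continue
        if math.gcd(math.gcd(abs(u[0]), abs(u[1])), abs(u[2])) != 1:
            continue
        # canonical sign: first nonzero component positive
        for x in u:
            if x:
                if x < 0:
                    break
                yield u
                break


def find_lattice_twofolds(
    cell: UnitCell, delta_tol: float = DEFAULT_DELTA_TOL, bound: int = 2
) -> list[LatticeTwofold]:
    """Le Page search for twofold axes of the lattice metric.

    Scans coprime integer direct axes ``t = u a + v b + w c`` against
    coprime reciprocal axes ``tau = h a* + k b* + l c*`` with
    ``t . tau in {1, 2}`` (the condition for the associated twofold
    ``W = 2 t tau^T / (t . tau) - I`` to be an integer lattice operation)
    and keeps pairs whose delta angle is within *delta_tol* degrees.
    """
    if not 0 <= delta_tol <= 5:
        raise ValueError("delta_tol must be within [0, 5] degrees")
    O = cell.orth
    Ostar = np.linalg.inv(O).T
    direct = list(_coprime_triples(bound))
    found: dict[tuple, LatticeTwofold] = {}
    for u in direct:
        t_cart = O @ np.array(u, dtype=float)
        for h in direct:
            dot = u[0] * h[0] + u[1] * h[1] + u[2] * h[2]
            if dot not in (1, 2):
                continue
            tau_cart = Ostar @ np.array(h, dtype=float)
            cosang = float(t_cart @ tau_cart /
                           (np.linalg.norm(t_cart) * np.linalg.norm(tau_cart)))
            delta = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
            if delta > delta_tol:
                continue
            W = [[Fraction(2 * u[i] * h[j], dot) - (1 if i == j else 0)
                  for j in range(3)] for i in range(3)]
            if any(v.denominator != 1 for row in W for v in row):
                continue
            op = RationalSymOp(tuple(tuple(row) for row in W))
            key = tuple(tuple(row) for row in op.W)
            if key not in found or delta < found[key].delta:
                found[key] = LatticeTwofold(u, h, delta, op)
    return sorted(found.values(), key=lambda tf: (tf.delta, tf.uvw))


# ---------------------------------------------------------------------------
# integer linear algebra helpers (exact, small systems)


def _integer_kernel_vector(M: np.ndarray) -> tuple[int, int, int]:
    """Primitive integer vector spanning the 1-d kernel of integer matrix M."""
    from fractions import Fraction as F

    rows = [[F(int(v)) for v in row] for row in np.asarray(M)]
    # Gaussian elimination
    pivots = []
    r = 0
    for c in range(3):
        piv = next((i for i in range(r, len(rows)) if rows[i][c] != 0), None)
        if piv is None:
            continue
        rows[r], rows[piv] = rows[piv], rows[r]
        rows[r] = [v / rows[r][c] for v in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
    free = [c for c in range(3) if c not in pivots]
    if len(free) != 1:
        raise ValueError("kernel is not one-dimensional")
    fc = free[0]
    vec = [F(0)] * 3
    vec[fc] = F(1)
    for rr, pc in enumerate(pivots):
        vec[pc] = -rows[rr][fc]
    den = math.lcm(*(v.denominator for v in vec))
    ints = [int(v * den) for v in vec]
    g = math.gcd(math.gcd(abs(ints[0]), abs(ints[1])), abs(ints[2]))
    ints = [v // g for v in ints]
    for x in ints:
        if x:
            if x < 0:
                ints = [-v for v in ints]
            break
    return tuple(ints)


def _rotation_axes(op: RationalSymOp) -> tuple[tuple[int, int, int], tuple[int, int, int]]:
    """(direct uvw, reciprocal hkl) integer axes of a proper rotation."""
    W = np.array([[int(v) for v in row] for row in op.W])
    u = _integer_kernel_vector(W - np.eye(3, dtype=int))
    h = _integer_kernel_vector(W.T - np.eye(3, dtype=int))
    return u, h


def _axis_delta(u, h, cell: UnitCell) -> float:
    t = cell.orth @ np.array(u, dtype=float)
    tau = np.linalg.inv(cell.orth).T @ np.array(h, dtype=float)
    cosang = float(t @ tau / (np.linalg.norm(t) * np.linalg.norm(tau)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


def _perp_lattice_basis(h, G: np.ndarray, bound: int = 6):
    """Two short independent lattice vectors v with h . v = 0, spanning the
    full rank-2 sublattice."""
    cands = []
    for v in itertools.product(range(-bound, bound + 1), repeat=3):
        if v == (0, 0, 0) or h[0] * v[0] + h[1] * v[1] + h[2] * v[2] != 0:
            continue
        length = float(np.array(v) @ G @ np.array(v))
        cands.append((length, v))
    cands.sort(key=lambda t: (t[0], t[1]))
    v1 = np.array(cands[0][1])
    v2 = None
    for _, v in cands[1:]:
        vv = np.array(v)
        if np.any(np.cross(v1, vv)):
            v2 = vv
            break
    if v2 is None:
        raise ValueError("could not find perpendicular lattice basis")
    # check primitivity of the sublattice basis: every enumerated in-plane
    # vector must be an integer combination of (v1, v2)
    B = np.column_stack([v1, v2]).astype(float)
    for _, v in cands:
        coef, *_ = np.linalg.lstsq(B, np.array(v, dtype=float), rcond=None)
        if not np.allclose(coef, np.rint(coef), atol=1e-8):
            # replace v2 by the offending shorter vector combination
            v2 = np.array(v)
            B = np.column_stack([v1, v2]).astype(float)
    return v1, v2


# ---------------------------------------------------------------------------
# subgroup enumeration and conventional settings


def _subgroup_sets(ops: tuple[RationalSymOp, ...]) -> list[frozenset[RationalSymOp]]:
    """All subgroups of a finite operator set (order <= 24 here)."""
    identity = RationalSymOp.identity()
    full = frozenset(ops)
    subgroups = {frozenset([identity])}
    frontier = {frozenset([identity])}
    while frontier:
        new = set()
        for S in frontier:
            for g in full - S:
                closed = _close(S | {g})
                if closed not in subgroups:
                    new.add(closed)
        subgroups |= new
        frontier = new
    return sorted(subgroups, key=lambda s: (len(s), sorted(g.sort_key() for g in s)))


def _close(ops: frozenset[RationalSymOp]) -> frozenset[RationalSymOp]:
    cur = set(ops)
    while True:
        new = {a * b for a in cur for b in cur} - cur
        if not new:
            return frozenset(cur)
        cur |= new


def _op_shorthand(g: RationalSymOp) -> str:
    if g.is_identity:
        return "1"
    order = g.rotation_order()
    u, _ = _rotation_axes(g)
    axis = "".join(str(x) for x in u) if any(abs(x) > 1 for x in u) or min(u) < 0 \
        else {"100": "x", "010": "y", "001": "z", "110": "xy", "011": "yz", "101": "xz"}.get(
            "".join(str(x) for x in u), "".join(str(x) for x in u))
    return f"{order}({axis})"


def _centring_cosets(M: np.ndarray) -> set[tuple[Fraction, ...]]:
    """Nonzero cosets of the old (primitive) lattice in the cell spanned by
    integer basis-column matrix M."""
    Mf = [[Fraction(int(v)) for v in row] for row in M]
    from .symmetry_core import _mat_inv  # exact rational inverse

    Minv = _mat_inv(tuple(tuple(row) for row in Mf))
    n = abs(int(round(float(np.linalg.det(M.astype(float))))))
    seen = set()
    for coeffs in itertools.product(range(-2, 3), repeat=3):
        v = tuple(
            sum(Minv[i][j] * coeffs[j] for j in range(3)) % 1 for i in range(3)
        )
        seen.add(v)
    seen.discard((Fraction(0), Fraction(0), Fraction(0)))
    assert len(seen) == n - 1, "centring coset enumeration incomplete"
    return seen


_C_FACE = (Fraction(1, 2), Fraction(1, 2), Fraction(0))
_A_FACE = (Fraction(0), Fraction(1, 2), Fraction(1, 2))
_B_FACE = (Fraction(1, 2), Fraction(0), Fraction(1, 2))
_BODY = (Fraction(1, 2), Fraction(1, 2), Fraction(1, 2))


def _classify_centring(cosets: set) -> str:
    if not cosets:
        return "P"
    if cosets == {_BODY}:
        return "I"
    if cosets == {_C_FACE}:
        return "C"
    if cosets == {_A_FACE}:
        return "A"
    if cosets == {_B_FACE}:
        return "B"
    if cosets == {_A_FACE, _B_FACE, _C_FACE}:
        return "F"
    thirds = {v for v in cosets if all(x.denominator in (1, 3) for x in v)}
    if len(cosets) == 2 and thirds == cosets:
        return "R"
    return "?"


def _order_partition(S) -> dict[int, int]:
    out: dict[int, int] = {}
    for g in S:
        out[g.rotation_order()] = out.get(g.rotation_order(), 0) + 1
    return out


@dataclass
class _Frame:
    symbol: str          # Patterson symbol (catalogue style, e.g. "C2/m")
    M: np.ndarray        # integer basis columns, conventional in reduced frame
    centring: str
    axis_note: str = ""


def _conventional_frame(S: frozenset[RationalSymOp], G: np.ndarray) -> _Frame:
    """Conventional Patterson frame of a rotation subgroup on the lattice.

    ``S`` is a group of integer rotation matrices in the reduced primitive
    basis with metric ``G``; returns the conventional basis (columns, as
    integer combinations of the reduced basis vectors) and the Patterson
    symbol (centring + Laue class).
    """
    n = len(S)
    orders = _order_partition(S)
    elems = sorted(S, key=RationalSymOp.sort_key)
    nontriv = [g for g in elems if not g.is_identity]

    if n == 1:
        return _Frame("P-1", np.eye(3, dtype=int), "P")

    def axes_of_order(k):
        seen = {}
        for g in nontriv:
            if g.rotation_order() == k:
                u, h = _rotation_axes(g)
                seen.setdefault(u, (u, h))
        return list(seen.values())

    if n == 2:
        (u, h), = axes_of_order(2)
        return _monoclinic_frame(u, h, G)

    if n == 4 and orders.get(4):
        return _principal_axis_frame(S, 4, G, "4/m", {1: "P", 2: "I"})
    if n == 4:
        return _orthorhombic_frame([a for a, _ in axes_of_order(2)], G, "mmm")
    if n == 3:
        return _principal_axis_frame(S, 3, G, "-3", {1: "P", 3: "R"})
    if n == 6 and orders.get(6):
        return _principal_axis_frame(S, 6, G, "6/m", {1: "P"})
    if n == 6 and orders.get(3):
        return _d3_frame(S, G)
    if n == 8 and orders.get(4):
        return _dihedral_frame(S, 4, G, "4/mmm", {1: "P", 2: "I"})
    if n == 12 and orders.get(6):
        return _dihedral_frame(S, 6, G, "6/mmm", {1: "P"})
    if n == 12:
        return _orthorhombic_frame([a for a, _ in axes_of_order(2)], G, "m-3")
    if n == 24:
        fours = axes_of_order(4)
        return _orthorhombic_frame([a for a, _ in fours], G, "m-3m")
    raise ValueError(f"unrecognized rotation group of order {n}")


def _monoclinic_frame(u, h, G) -> _Frame:
    v1, v2 = _perp_lattice_basis(h, G)
    M = np.column_stack([v1, np.array(u), v2]).astype(int)
    if round(float(np.linalg.det(M.astype(float)))) < 0:
        M[:, 2] = -M[:, 2]
    # normalize centring to P or C (b-unique conventions)
    for _ in range(4):
        cosets = _centring_cosets(M)
        letter = _classify_centring(cosets)
        if letter in ("P", "C"):
            return _Frame("P2/m" if letter == "P" else "C2/m", M, letter,
                          axis_note=f"2 along [{u[0]}{u[1]}{u[2]}]")
        if letter == "A":        # swap a and c (keep handedness)
            M = np.column_stack([-M[:, 2], M[:, 1], -M[:, 0]]).astype(int)
        elif letter == "B":      # absorb (a+c)/2: smaller primitive cell
            newc = (M[:, 0] + M[:, 2]) // 2 if not np.any((M[:, 0] + M[:, 2]) % 2) \
                else M[:, 0] + M[:, 2]
            M = np.column_stack([M[:, 0], M[:, 1], newc]).astype(int)
        elif letter == "I":      # I -> C via c' = a + c
            M = np.column_stack([M[:, 0], M[:, 1], M[:, 0] + M[:, 2]]).astype(int)
        else:
            break
    raise ValueError("monoclinic centring normalization failed")


def _orthorhombic_frame(axes, G, laue) -> _Frame:
    axes = [np.array(a) for a in axes]
    assert len(axes) == 3
    # sort by length for a <= b <= c flavour; enforce right-handedness
    axes.sort(key=lambda v: float(v @ G @ v))
    M = np.column_stack(axes).astype(int)
    if round(float(np.linalg.det(M.astype(float)))) < 0:
        M[:, 0] = -M[:, 0]
    cosets = _centring_cosets(M)
    letter = _classify_centring(cosets)
    if letter in ("A", "B"):  # permute axes cyclically so the face is C
        perm = {"A": [1, 2, 0], "B": [2, 0, 1]}[letter]
        M = M[:, perm]
        if round(float(np.linalg.det(M.astype(float)))) < 0:
            M[:, 0] = -M[:, 0]
        letter = _classify_centring(_centring_cosets(M))
    if laue == "mmm" and letter not in ("P", "C", "I", "F"):
        raise ValueError(f"unexpected orthorhombic centring {letter!r}")
    return _Frame(f"{letter}{laue}", M, letter)


def _principal_axis_frame(S, order, G, laue, letters) -> _Frame:
    """Cyclic group frame: c along the principal axis, a shortest in-plane."""
    rots = [g for g in S if g.rotation_order() == order]
    g0 = rots[0]
    u, h = _rotation_axes(g0)
    v1, v2 = _perp_lattice_basis(h, G)
    a = v1 if float(v1 @ G @ v1) <= float(v2 @ G @ v2) else v2
    M = _ab_frame(S, a, u, G, order)
    letter = _classify_centring(_centring_cosets(M))
    if letter not in letters.values():
        raise ValueError(f"unexpected centring {letter!r} for {laue}")
    return _Frame(f"{letter}{laue}", M, letter)


def _ab_frame(S, a, u, G, order) -> np.ndarray:
    """Basis [a, b, u] with b a symmetry image of a at the conventional
    angle (120 deg for the hexagonal family, 90 deg otherwise)."""
    target = -0.5 if order in (3, 6) else 0.0
    best = None
    for g in S:
        W = np.array([[int(x) for x in row] for row in g.W])
        b = W @ a
        M = np.column_stack([a, b, np.array(u)]).astype(int)
        det = round(float(np.linalg.det(M.astype(float))))
        if det == 0:
            continue
        if det < 0:
            M[:, 2] = -M[:, 2]
            det = -det
        cosang = float(a @ G @ b) / math.sqrt(float(a @ G @ a) * float(b @ G @ b))
        score = abs(cosang - target)
        if best is None or (round(score, 6), det) < best[0]:
            best = ((round(score, 6), det), M)
    if best is None:
        raise ValueError("no principal-axis frame found")
    return best[1]


def _dihedral_frame(S, order, G, laue, letters) -> _Frame:
    """Dihedral group frame: c along principal axis, a along an in-plane
    twofold (the choice minimizing cell volume, then length)."""
    rots = [g for g in S if g.rotation_order() == order]
    g0 = rots[0]
    u, h = _rotation_axes(g0)
    candidates = []
    for g in S:
        if g.rotation_order() != 2:
            continue
        v, _ = _rotation_axes(g)
        if h[0] * v[0] + h[1] * v[1] + h[2] * v[2] != 0:
            continue
        a = np.array(v)
        try:
            M = _ab_frame(S, a, u, G, order)
        except ValueError:
            continue
        det = round(float(np.linalg.det(M.astype(float))))
        candidates.append((det, float(a @ G @ a), M.tolist()))
    if not candidates:
        raise ValueError("no in-plane twofold frame found")
    candidates.sort(key=lambda t: (t[0], t[1]))
    M = np.array(candidates[0][2], dtype=int)
    letter = _classify_centring(_centring_cosets(M))
    if letter not in letters.values():
        raise ValueError(f"unexpected centring {letter!r} for {laue}")
    return _Frame(f"{letter}{laue}", M, letter)


def _d3_frame(S, G) -> _Frame:
    """Order-6 dihedral-of-threefold group: distinguish -3m1 / -31m / R-3m."""
    threes = [g for g in S if g.rotation_order() == 3]
    g0 = threes[0]
    u, h = _rotation_axes(g0)
    v1, v2 = _perp_lattice_basis(h, G)
    a = v1 if float(v1 @ G @ v1) <= float(v2 @ G @ v2) else v2
    best = None
    for gk in (g0, g0.inverse()):
        W = np.array([[int(x) for x in row] for row in gk.W])
        b = W @ a
        M = np.column_stack([a, b, np.array(u)]).astype(int)
        det = round(float(np.linalg.det(M.astype(float))))
        if det == 0:
            continue
        if det < 0:
            M[:, 2] = -M[:, 2]
            det = -det
        cosang = float(a @ G @ b) / math.sqrt(float(a @ G @ a) * float(b @ G @ b))
        if best is None or (abs(cosang + 0.5), det) < best[0]:
            best = ((abs(cosang + 0.5), det), M, det)
    _, M, det = best
    letter = _classify_centring(_centring_cosets(M))
    if letter == "R":
        return _Frame("R-3m", M, "R")
    # orientation of the twofolds relative to the hexagonal a axis
    Minv = np.linalg.inv(M.astype(float))
    hexa = {tuple(int(round(x)) for x in Minv @ M[:, 0])}  # (1,0,0)
    along_a = False
    for g in S:
        if g.rotation_order() != 2:
            continue
        v, _ = _rotation_axes(g)
        vc = Minv @ np.array(v, dtype=float)
        vc = vc / np.max(np.abs(vc[np.abs(vc) > 1e-9]))
        vi = np.rint(vc)
        if not np.allclose(vc, vi, atol=1e-6):
            continue
        vi = tuple(int(x) for x in vi)
        if vi in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (1, 1, 0), (-1, -1, 0)):
            along_a = True
    sym = "P-3m1" if along_a else "P-31m"
    return _Frame(sym, M, "P")


_LAUE_SYSTEM = {
    "-1": "triclinic", "2/m": "monoclinic", "mmm": "orthorhombic",
    "4/m": "tetragonal", "4/mmm": "tetragonal", "-3": "trigonal",
    "-3m1": "trigonal", "-31m": "trigonal", "-3m": "trigonal",
    "6/m": "hexagonal", "6/mmm": "hexagonal",
    "m-3": "cubic", "m-3m": "cubic",
}


def idealize_cell(cell: UnitCell, laue: str, centring: str) -> UnitCell:
    """Symmetrize cell parameters to the constraints of a Laue class."""
    a, b, c, al, be, ga = cell.parameters
    system = _LAUE_SYSTEM[laue if not laue.startswith("R") else "-3"]
    if centring == "R" and system == "trigonal":
        system = "trigonal"
    if system == "triclinic":
        return cell
    if system == "monoclinic":
        return UnitCell(a, b, c, 90.0, be, 90.0)
    if system == "orthorhombic":
        return UnitCell(a, b, c, 90.0, 90.0, 90.0)
    if system == "tetragonal":
        ab = 0.5 * (a + b)
        return UnitCell(ab, ab, c, 90.0, 90.0, 90.0)
    if system in ("trigonal", "hexagonal"):
        ab = 0.5 * (a + b)
        return UnitCell(ab, ab, c, 90.0, 90.0, 120.0)
    if system == "cubic":
        abc = (a + b + c) / 3.0
        return UnitCell(abc, abc, abc, 90.0, 90.0, 90.0)
    raise AssertionError(system)


def enumerate_patterson_settings(
    reduced_cell: UnitCell,
    twofolds: list[LatticeTwofold],
    n_chains_p1: int,
) -> list[PattersonSetting]:
    """All Patterson settings compatible with the reduced cell.

    Builds the metric rotation group generated by the accepted twofolds
    (higher-order axes arise as products of twofolds), enumerates its
    rotation subgroups, assigns each a conventional frame, and reports
    one setting per distinct operator set.  The trivial P-1 setting is
    always present with max_delta 0.
    """
    G = reduced_cell.metric
    active = list(twofolds)
    while True:
        try:
            lattice_group = group_closure([tf.operator for tf in active])
        except ValueError:
            lattice_group = None
        if lattice_group is not None and lattice_group.order <= 24:
            break
        active = active[:-1]  # drop the worst-delta twofold and retry
    settings = []
    for S in _subgroup_sets(lattice_group.operators):
        frame = _conventional_frame(S, G)
        if n_chains_p1 % len(S):
            continue
        deltas = [0.0]
        for g in S:
            if g.is_identity:
                continue
            u, h = _rotation_axes(g)
            deltas.append(_axis_delta(u, h, reduced_cell))
        Mfrac = tuple(tuple(Fraction(int(v)) for v in row) for row in frame.M)
        cb = ChangeOfBasisOp(Mfrac).inverse()
        conv_cell = idealize_cell(
            reduced_cell.changed_basis(cb), frame.symbol[1:], frame.centring
        )
        settings.append(
            PattersonSetting(
                patterson_symbol=frame.symbol,
                cb_from_input=cb,
                rotational_operators=tuple(sorted(S, key=RationalSymOp.sort_key)),
                max_delta=max(deltas),
                n_chains_in_asu=n_chains_p1 // len(S),
                conventional_cell=conv_cell,
                centring=frame.centring,
                axis_note=frame.axis_note,
            )
        )
    settings.sort(key=lambda s: (-s.rotation_order, s.patterson_symbol, s.max_delta))
    return settings
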