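"""Exact space-group algebra over the rationals.

Symmetry operations and change-of-basis operators are kept as exact
rational matrices (:class:`fractions.Fraction`) so that group closure,
subgroup tests and left coset decompositions are free of floating-point
drift.  The catalogue of the 65 Sohncke space groups -- the only groups a
chiral macromolecule can crystallize in -- is sourced from gemmi's
space-group table and re-expressed in this exact algebra.

Conventions
-----------
* An operator ``g = (W, w)`` acts on fractional coordinates as
  ``x' = W x + w``; translations are canonicalized into ``[0, 1)``.
* A change of basis ``cb = (R, T)`` maps fractional coordinates of the
  old frame to the new frame, ``x_new = R x_old + T``; row-vector Miller
  indices transform contravariantly as ``H_new = H R^{-1}``.
* Operators serialize to/from the xyz-triplet dialect used in PDB
  REMARK 290 and mmCIF ``_symmetry_equiv_pos_as_xyz``.
"""

from __future__ import annotations

import functools
import itertools
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "RationalSymOp",
    "ChangeOfBasisOp",
    "SpaceGroupDef",
    "CosetDecomposition",
    "group_closure",
    "left_cosets",
    "candidate_space_groups",
    "standardize_setting",
    "sohncke_catalogue",
    "patterson_symbol_of",
]

_MAX_GROUP_ORDER = 192

Frac3x3 = tuple[tuple[Fraction, ...], ...]
Frac3 = tuple[Fraction, ...]


def _frac_mat(m) -> Frac3x3:
    return tuple(tuple(Fraction(v) for v in row) for row in m)


def _frac_vec(v) -> Frac3:
    return tuple(Fraction(x) for x in v)


def _mat_mul(a: Frac3x3, b: Frac3x3) -> Frac3x3:
    return tuple(
        tuple(sum(a[i][k] * b[k][j] for k in range(3)) for j in range(3))
        for i in range(3)
    )


def _mat_vec(a: Frac3x3, v: Frac3) -> Frac3:
    return tuple(sum(a[i][k] * v[k] for k in range(3)) for i in range(3))


def _vec_add(u: Frac3, v: Frac3) -> Frac3:
    return tuple(a + b for a, b in zip(u, v))


def _det(m: Frac3x3) -> Fraction:
    return (
        m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
        - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
        + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
    )


def _mat_inv(m: Frac3x3) -> Frac3x3:
    d = _det(m)
    if d == 0:
        raise ValueError("matrix is singular")
    cof = [
        [
            (m[(i + 1) % 3][(j + 1) % 3] * m[(i + 2) % 3][(j + 2) % 3]
             - m[(i + 1) % 3][(j + 2) % 3] * m[(i + 2) % 3][(j + 1) % 3])
            for i in range(3)
        ]
        for j in range(3)
    ]
    return tuple(tuple(c / d for c in row) for row in cof)


def _mod1(v: Frac3) -> Frac3:
    return tuple(x - (x // 1) for x in v)


_IDENTITY_MAT: Frac3x3 = _frac_mat([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
_ZERO_VEC: Frac3 = _frac_vec([0, 0, 0])

_AXES = "xyz"
_TERM_RE = re.compile(r"([+-]?)(\d+(?:/\d+)?\*?)?([xyz])|([+-]?\d+(?:/\d+)?)")


def _parse_triplet_component(comp: str) -> tuple[list[Fraction], Fraction]:
    row = [Fraction(0)] * 3
    trans = Fraction(0)
    pos = 0
    comp = comp.replace(" ", "")
    while pos < len(comp):
        m = _TERM_RE.match(comp, pos)
        if not m:
            raise ValueError(f"cannot parse triplet component {comp!r}")
        pos = m.end()
        if m.group(3):
            sign = -1 if m.group(1) == "-" else 1
            coef = Fraction(m.group(2).rstrip("*")) if m.group(2) else Fraction(1)
            row[_AXES.index(m.group(3))] += sign * coef
        else:
            trans += Fraction(m.group(4))
        # handle trailing '/den' applying to a preceding symbol, e.g. "x/2"
        if pos < len(comp) and comp[pos] == "/":
            m2 = re.match(r"/(\d+)", comp[pos:])
            den = Fraction(int(m2.group(1)))
            if m.group(3):
                row[_AXES.index(m.group(3))] /= den
            else:
                trans /= den
            pos += m2.end()
    return row, trans


def _parse_triplet(triplet: str) -> tuple[Frac3x3, Frac3]:
    comps = triplet.split(",")
    if len(comps) != 3:
        raise ValueError(f"triplet must have three components: {triplet!r}")
    rows, trans = [], []
    for comp in comps:
        row, t = _parse_triplet_component(comp)
        rows.append(tuple(row))
        trans.append(t)
    return tuple(rows), tuple(trans)


def _fmt_frac(f: Fraction) -> str:
    return str(f.numerator) if f.denominator == 1 else f"{f.numerator}/{f.denominator}"


def _triplet_from(W: Frac3x3, w: Frac3) -> str:
    parts = []
    for i in range(3):
        s = ""
        for j, ax in enumerate(_AXES):
            c = W[i][j]
            if c == 0:
                continue
            sign = "-" if c < 0 else ("+" if s else "")
            mag = abs(c)
            coef = "" if mag == 1 else _fmt_frac(mag) + "*"
            s += f"{sign}{coef}{ax}"
        t = w[i]
        if t != 0 or not s:
            sign = "-" if t < 0 else ("+" if s else "")
            s += f"{sign}{_fmt_frac(abs(t))}"
        parts.append(s)
    return ",".join(parts)


@dataclass(frozen=True)
class RationalSymOp:
    """A symmetry operation ``x -> W x + w`` with exact rational entries.

    ``W`` is the rotation part (det +/-1), ``w`` the translation part,
    canonicalized into ``[0, 1)``.
    """

    W: Frac3x3
    w: Frac3 = _ZERO_VEC

    def __post_init__(self):
        object.__setattr__(self, "W", _frac_mat(self.W))
        object.__setattr__(self, "w", _mod1(_frac_vec(self.w)))
        if abs(_det(self.W)) != 1:
            raise ValueError(f"rotation part must have determinant +/-1, got {_det(self.W)}")

    # -- construction ------------------------------------------------
    @classmethod
    def identity(cls) -> "RationalSymOp":
        return cls(_IDENTITY_MAT, _ZERO_VEC)

    @classmethod
    def from_triplet(cls, triplet: str) -> "RationalSymOp":
        return cls(*_parse_triplet(triplet))

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "RationalSymOp":
        den = gemmi.Op.DEN
        W = tuple(tuple(Fraction(v, den) for v in row) for row in op.rot)
        w = tuple(Fraction(v, den) for v in op.tran)
        return cls(W, w)

    # -- algebra -----------------------------------------------------
    def __mul__(self, other: "RationalSymOp") -> "RationalSymOp":
        """Composition: (self * other)(x) = self(other(x))."""
        return RationalSymOp(
            _mat_mul(self.W, other.W), _vec_add(_mat_vec(self.W, other.w), self.w)
        )

    def inverse(self) -> "RationalSymOp":
        Winv = _mat_inv(self.W)
        return RationalSymOp(Winv, tuple(-x for x in _mat_vec(Winv, self.w)))

    def det(self) -> int:
        return int(_det(self.W))

    @property
    def is_identity(self) -> bool:
        return self.W == _IDENTITY_MAT and all(x == 0 for x in self.w)

    def rotation_order(self) -> int:
        """Smallest n >= 1 with W^n = I (rotation part only)."""
        m = self.W
        for n in range(1, 7):
            if m == _IDENTITY_MAT:
                return n
            m = _mat_mul(m, self.W)
        raise ValueError("rotation part is not of crystallographic order")

    # -- actions -----------------------------------------------------
    def rot_array(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.W])

    def tran_array(self) -> np.ndarray:
        return np.array([float(v) for v in self.w])

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates, shape (..., 3)."""
        return frac @ self.rot_array().T + self.tran_array()

    def apply_to_miller(self, hkl: np.ndarray) -> np.ndarray:
        """Row-vector Miller indices transform as H' = H W."""
        out = np.asarray(hkl) @ self.rot_array()
        return np.rint(out).astype(np.int64)

    def triplet(self) -> str:
        return _triplet_from(self.W, self.w)

    def to_gemmi(self) -> gemmi.Op:
        return gemmi.Op(self.triplet())

    def sort_key(self):
        flat = tuple(v for row in self.W for v in row)
        return (flat, self.w)

    def __repr__(self) -> str:
        return f"RationalSymOp('{self.triplet()}')"


@dataclass(frozen=True)
class ChangeOfBasisOp:
    """Invertible affine frame change ``x_new = R x_old + T`` (exact rationals)."""

    R: Frac3x3
    T: Frac3 = _ZERO_VEC

    def __post_init__(self):
        object.__setattr__(self, "R", _frac_mat(self.R))
        object.__setattr__(self, "T", _frac_vec(self.T))
        if _det(self.R) == 0:
            raise ValueError("change-of-basis rotation part is singular")

    @classmethod
    def identity(cls) -> "ChangeOfBasisOp":
        return cls(_IDENTITY_MAT, _ZERO_VEC)

    @classmethod
    def from_triplet(cls, triplet: str) -> "ChangeOfBasisOp":
        return cls(*_parse_triplet(triplet))

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "ChangeOfBasisOp":
        den = gemmi.Op.DEN
        R = tuple(tuple(Fraction(v, den) for v in row) for row in op.rot)
        T = tuple(Fraction(v, den) for v in op.tran)
        return cls(R, T)

    def inverse(self) -> "ChangeOfBasisOp":
        Rinv = _mat_inv(self.R)
        return ChangeOfBasisOp(Rinv, tuple(-x for x in _mat_vec(Rinv, self.T)))

    def __mul__(self, other: "ChangeOfBasisOp") -> "ChangeOfBasisOp":
        """Composition: (self * other)(x) = self(other(x))."""
        return ChangeOfBasisOp(
            _mat_mul(self.R, other.R), _vec_add(_mat_vec(self.R, other.T), self.T)
        )

    def det(self) -> Fraction:
        return _det(self.R)

    # -- actions -----------------------------------------------------
    def rot_array(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.R])

    def tran_array(self) -> np.ndarray:
        return np.array([float(v) for v in self.T])

    def apply_to_coords(self, frac: np.ndarray) -> np.ndarray:
        return frac @ self.rot_array().T + self.tran_array()

    def apply_to_miller(self, hkl: np.ndarray) -> np.ndarray:
        """Miller indices transform contravariantly: H' = H R^{-1}."""
        rinv = np.array([[float(v) for v in row] for row in _mat_inv(self.R)])
        out = np.asarray(hkl, dtype=float) @ rinv
        rounded = np.rint(out)
        if not np.allclose(out, rounded, atol=1e-9):
            raise ValueError("change of basis does not map Miller indices to integers")
        return rounded.astype(np.int64)

    def apply_to_op(self, g: RationalSymOp) -> RationalSymOp:
        """Conjugate a symmetry operation into the new frame."""
        Rinv = _mat_inv(self.R)
        W = _mat_mul(self.R, _mat_mul(g.W, Rinv))
        w = _vec_add(
            _mat_vec(self.R, _vec_add(g.w, _mat_vec(g.W, tuple(-x for x in _mat_vec(Rinv, self.T))))),
            self.T,
        )
        return RationalSymOp(W, w)

    def apply_to_metric(self, G: np.ndarray) -> np.ndarray:
        """Metric tensor of the new cell: G' = R^{-T} G R^{-1}."""
        rinv = np.array([[float(v) for v in row] for row in _mat_inv(self.R)])
        return rinv.T @ np.asarray(G) @ rinv

    def triplet(self) -> str:
        return _triplet_from(self.R, self.T)

    def __repr__(self) -> str:
        return f"ChangeOfBasisOp('{self.triplet()}')"


_CRYSTAL_SYSTEMS = (
    "triclinic", "monoclinic", "orthorhombic", "tetragonal",
    "trigonal", "hexagonal", "cubic",
)


@dataclass(frozen=True)
class SpaceGroupDef:
    """A finite space group: symbol plus the full operator set.

    ``operators`` contains every operation of one unit cell, i.e. point
    operations combined with centring translations, so ``len(operators)``
    equals point-group order times centring multiplicity.
    """

    symbol: str
    operators: tuple[RationalSymOp, ...]
    sohncke: bool
    patterson_symbol: str
    crystal_system: str
    number: int = 0
    hall: str = ""

    def __post_init__(self):
        ops = tuple(sorted(set(self.operators), key=RationalSymOp.sort_key))
        object.__setattr__(self, "operators", ops)

    @property
    def order(self) -> int:
        return len(self.operators)

    def rotation_parts(self) -> list[Frac3x3]:
        return sorted({g.W for g in self.operators})

    @functools.lru_cache(maxsize=None)
    def _op_set(self) -> frozenset[RationalSymOp]:
        return frozenset(self.operators)

    def __contains__(self, g: RationalSymOp) -> bool:
        return g in self._op_set()

    def is_subgroup(self, other: "SpaceGroupDef") -> bool:
        """True if every operator of *self* belongs to *other* (same frame)."""
        return all(g in other for g in self.operators)

    def transformed(self, cb: ChangeOfBasisOp, symbol: str | None = None) -> "SpaceGroupDef":
        ops = tuple(cb.apply_to_op(g) for g in self.operators)
        return SpaceGroupDef(
            symbol if symbol is not None else self.symbol,
            ops, self.sohncke, self.patterson_symbol, self.crystal_system,
            self.number, self.hall,
        )

    @classmethod
    def from_gemmi(cls, sg: gemmi.SpaceGroup) -> "SpaceGroupDef":
        ops = tuple(RationalSymOp.from_gemmi(op) for op in sg.operations())
        return cls(
            symbol=sg.xhm(),
            operators=ops,
            sohncke=sg.is_sohncke(),
            patterson_symbol=patterson_symbol_of(sg),
            crystal_system=sg.crystal_system_str(),
            number=sg.number,
            hall=sg.hall,
        )

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroupDef":
        """Look up a Hermann-Mauguin symbol (short or extended) in the catalogue.

        Only Sohncke groups are accepted; anything else raises ``ValueError``.
        """
        sg = _find_gemmi_group(symbol)
        if sg is None:
            raise ValueError(f"unknown space-group symbol {symbol!r}")
        if not sg.is_sohncke():
            raise ValueError(
                f"space group {symbol!r} is not a Sohncke group; "
                "chiral macromolecules cannot adopt it"
            )
        return cls.from_gemmi(sg)

    def __repr__(self) -> str:
        return f"SpaceGroupDef({self.symbol!r}, order={self.order})"


def _find_gemmi_group(symbol: str) -> gemmi.SpaceGroup | None:
    s = symbol.strip()
    sg = gemmi.find_spacegroup_by_name(s)
    if sg is not None:
        return sg
    # PDB files often write screw axes without spacing, e.g. "P212121"
    spaced = re.sub(r"(?<=[0-9A-Za-z])(?=[0-9])", " ", s)
    return gemmi.find_spacegroup_by_name(spaced)


def patterson_symbol_of(sg: gemmi.SpaceGroup) -> str:
    """Patterson symmetry symbol: centring letter + Laue class.

    Trigonal Laue class ``-3m`` is disambiguated into ``-3m1`` / ``-31m``
    from the point group (the two settings have differently oriented
    twofolds and are distinct Patterson symmetries).
    """
    laue = sg.laue_str()
    cen = sg.centring_type()
    if laue == "-3m" and cen in ("P", "H"):
        # orientation of the secondary direction is read off the H-M symbol:
        # P321/P3m1-type groups belong to -3m1, P312/P31m-type to -31m
        parts = sg.xhm().split()
        laue = "-31m" if len(parts) >= 3 and parts[2] == "1" else "-3m1"
    return f"{cen}{laue}"


@functools.lru_cache(maxsize=1)
def sohncke_catalogue() -> tuple[SpaceGroupDef, ...]:
    """The 65 Sohncke space groups, reference settings, by IT number."""
    seen: dict[int, SpaceGroupDef] = {}
    for sg in gemmi.spacegroup_table():
        if sg.is_sohncke() and sg.number not in seen and sg.is_reference_setting():
            seen[sg.number] = SpaceGroupDef.from_gemmi(sg)
    cat = tuple(seen[n] for n in sorted(seen))
    assert len(cat) == 65
    return cat


def group_closure(
    generators: Iterable[RationalSymOp],
    centrings: Iterable[Sequence] = (),
    symbol: str = "?",
) -> SpaceGroupDef:
    """Smallest closed group containing *generators* and *centrings*.

    Centring vectors are rational fractional translations added as pure
    translation operators.  Raises if the closure exceeds 192 elements
    (runaway input, e.g. a non-crystallographic rotation).
    """
    ops = {RationalSymOp.identity()}
    for g in generators:
        ops.add(g)
    for c in centrings:
        ops.add(RationalSymOp(_IDENTITY_MAT, _frac_vec(c)))
    while True:
        new = set()
        for a in ops:
            for b in ops:
                p = a * b
                if p not in ops:
                    new.add(p)
        if not new:
            break
        ops |= new
        if len(ops) > _MAX_GROUP_ORDER:
            raise ValueError(
                f"group closure exceeded {_MAX_GROUP_ORDER} elements; "
                "generators are not crystallographic"
            )
    # closure under inversion is implied for finite closed sets, but verify
    for g in ops:
        assert g.inverse() in ops
    proper = all(g.det() == 1 for g in ops)
    return SpaceGroupDef(symbol, tuple(ops), proper, "", "", 0, "")


@dataclass(frozen=True)
class CosetDecomposition:
    """Left coset decomposition of G with respect to a subgroup H.

    ``representatives`` excludes the identity coset (H itself); each is
    the lexicographically smallest element of its coset so the choice is
    deterministic.
    """

    group: SpaceGroupDef
    subgroup: SpaceGroupDef
    representatives: tuple[RationalSymOp, ...]

    @property
    def n_cosets(self) -> int:
        return len(self.representatives) + 1

    def all_representatives(self) -> tuple[RationalSymOp, ...]:
        """Identity first, then the nontrivial representatives."""
        return (RationalSymOp.identity(),) + self.representatives


def left_cosets(
    G: SpaceGroupDef,
    H: SpaceGroupDef,
    cb: ChangeOfBasisOp | None = None,
) -> CosetDecomposition:
    """Decompose G into left cosets of H (H transformed by *cb* first).

    Raises ``ValueError`` naming the first offending operator if the
    transformed H is not a subgroup of G.
    """
    if cb is not None:
        H = H.transformed(cb)
    for h in H.operators:
        if h not in G:
            raise ValueError(
                f"H is not a subgroup of G: operator '{h.triplet()}' of H "
                f"is not in {G.symbol}"
            )
    if G.order % H.order:
        raise ValueError("subgroup order does not divide group order")
    remaining = set(G.operators)
    cosets: list[list[RationalSymOp]] = []
    for g in sorted(G.operators, key=RationalSymOp.sort_key):
        if g not in remaining:
            continue
        coset = sorted((g * h for h in H.operators), key=RationalSymOp.sort_key)
        for el in coset:
            remaining.discard(el)
        cosets.append(coset)
    reps = []
    identity_seen = False
    for coset in cosets:
        rep = coset[0]
        if RationalSymOp.identity() in coset:
            identity_seen = True
            continue
        reps.append(rep)
    assert identity_seen
    reps.sort(key=RationalSymOp.sort_key)
    return CosetDecomposition(G, H, tuple(reps))


def candidate_space_groups(patterson_symbol: str) -> list[SpaceGroupDef]:
    """All Sohncke space groups with the given Patterson symmetry.

    Returned in fixed catalogue (IT-number) order; enantiomorphic pairs
    are both present.
    """
    hits = [g for g in sohncke_catalogue() if g.patterson_symbol == patterson_symbol]
    if not hits:
        known = sorted({g.patterson_symbol for g in sohncke_catalogue()})
        raise ValueError(
            f"unknown Patterson symbol {patterson_symbol!r}; known: {known}"
        )
    return hits


def standardize_setting(G: SpaceGroupDef) -> tuple[SpaceGroupDef, ChangeOfBasisOp]:
    """Map a (possibly nonstandard-setting) group to its reference setting.

    Returns the catalogue group and the change of basis carrying
    coordinates from the nonstandard frame to the conventional frame.
    Already-conventional groups return an identity cb.
    """
    target_ops = frozenset(G.operators)
    # fast path: operator-set equality with a reference setting
    for ref in sohncke_catalogue():
        if frozenset(ref.operators) == target_ops:
            return ref, ChangeOfBasisOp.identity()
    # search gemmi's table of alternative settings for a matching operator set
    for sg in gemmi.spacegroup_table():
        if not sg.is_sohncke():
            continue
        ops = frozenset(RationalSymOp.from_gemmi(op) for op in sg.operations())
        if ops == target_ops:
            ref = gemmi.get_spacegroup_reference_setting(sg.number)
            # gemmi: setting ops = basisop . ref ops . basisop^-1, with basisop
            # acting on coordinates as x_setting = basisop(x_ref)
            cb = ChangeOfBasisOp.from_gemmi(sg.basisop).inverse()
            return SpaceGroupDef.from_gemmi(ref), cb
    raise ValueError(f"no catalogue match for operator set of {G.symbol!r}")
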