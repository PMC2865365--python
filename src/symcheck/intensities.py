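"""Reflection intensities and the symmetry-operator reliability R_symop.

The central statistic scores a candidate rotational operator W by the
agreement of intensity pairs it relates:

    R_symop(W) = sum_pairs |I_H - I_HW| / sum_pairs (I_H + I_HW)

where the sums run over all pairs of reflections (H, H W) present in a
P1-expanded data set (Friedel mates are treated as equivalent
throughout).  R_symop is ~0 for a true symmetry operator and rises to
~constant for an unrelated pairing; values up to 25% are conventionally
tolerated for genuine operators measured with noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .lattice_symmetry import PattersonSetting, UnitCell
from .model import ScattererModel
from .symmetry_core import RationalSymOp, SpaceGroupDef

__all__ = [
    "ReflectionSet",
    "NoPairsError",
    "hemisphere_indices",
    "calc_structure_factors",
    "expand_obs_to_p1",
    "merge_under_group",
    "r_symop",
    "score_patterson_settings",
]

DEFAULT_D_MIN = 3.5  # Angstrom


class NoPairsError(ValueError):
    """Raised when an operator relates no reflection pairs in the data."""


def friedel_canonical(hkl: np.ndarray) -> np.ndarray:
    """Map each index to the canonical member of its Friedel pair.

    Canonical hemisphere: h > 0, or h == 0 and k > 0, or h == k == 0 and
    l >= 0.
    """
    h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    flip = (h[:, 0] < 0) | ((h[:, 0] == 0) & (h[:, 1] < 0)) | (
        (h[:, 0] == 0) & (h[:, 1] == 0) & (h[:, 2] < 0)
    )
    out = h.copy()
    out[flip] = -out[flip]
    return out


@dataclass
class ReflectionSet:
    """Merged reflection data tied to a cell and a merging symmetry."""

    cell: UnitCell
    symmetry: SpaceGroupDef
    hkl: np.ndarray                 # (N, 3) int
    I: np.ndarray                   # (N,)
    sigI: np.ndarray | None = None
    F: np.ndarray | None = None     # complex structure factors, if calculated
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.hkl = np.atleast_2d(np.asarray(self.hkl, dtype=np.int64))
        self.I = np.asarray(self.I, dtype=float)
        if len(self.hkl) != len(self.I):
            raise ValueError("hkl and I lengths differ")
        self._index = {tuple(h): i for i, h in enumerate(self.hkl)}
        if len(self._index) != len(self.hkl):
            raise ValueError("duplicate Miller indices in reflection set")

    @property
    def n_reflections(self) -> int:
        return len(self.hkl)

    @property
    def phases(self) -> np.ndarray:
        if self.F is None:
            raise ValueError("no phases: reflection set was not calculated")
        return np.angle(self.F)

    def lookup(self, hkl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of (canonicalized) hkl; mask marks found entries."""
        canon = friedel_canonical(hkl)
        idx = np.fromiter(
            (self._index.get(tuple(h), -1) for h in canon), dtype=np.int64,
            count=len(canon),
        )
        return idx, idx >= 0

    def d_spacings(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)


def hemisphere_indices(cell: UnitCell, d_min: float) -> np.ndarray:
    """All Friedel-unique Miller indices with d >= d_min (000 excluded)."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    # conservative per-axis bounds from the reciprocal metric diagonal
    gstar = np.linalg.inv(cell.metric)
    hmax = np.floor(1.0 / (d_min * np.sqrt(np.diag(gstar)))).astype(int) + 1
    axes = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = (H[:, 0] > 0) | ((H[:, 0] == 0) & (H[:, 1] > 0)) | (
        (H[:, 0] == 0) & (H[:, 1] == 0) & (H[:, 2] > 0)
    )
    H = H[keep]
    d = cell.d_spacing(H)
    H = H[d >= d_min]
    if len(H) == 0:
        raise ValueError(f"no reflections at d_min={d_min} for this cell")
    order = np.lexsort((H[:, 2], H[:, 1], H[:, 0]))
    return H[order]


def calc_structure_factors(
    model: ScattererModel, d_min: float = DEFAULT_D_MIN
) -> ReflectionSet:
    """Direct-summation structure factors of a P1 model.

    F(H) = sum_j w_j occ_j exp(-B_j s^2/4) exp(2 pi i H . x_j) over all
    sites, for the Friedel-unique hemisphere with d >= d_min.
    """
    H = hemisphere_indices(model.cell, d_min)
    amp = model.weight * model.occupancy
    if np.any(model.b_iso > 0):
        s2 = 1.0 / model.cell.d_spacing(H) ** 2  # (N_H,)
        damp = np.exp(-0.25 * np.outer(s2, model.b_iso))  # (N_H, N_at)
    else:
        damp = None
    phase = 2.0 * np.pi * (H @ model.sites.T)  # (N_H, N_atoms)
    contrib = np.exp(1j * phase)
    if damp is not None:
        contrib = contrib * damp
    F = contrib @ amp
    I = np.abs(F) ** 2
    return ReflectionSet(model.cell, SpaceGroupDef.from_symbol("P1"), H, I, F=F)


def expand_obs_to_p1(obs: ReflectionSet) -> tuple[ReflectionSet, int]:
    """Expand merged observations to P1 intensities.

    Every symmetry equivalent (rotation parts of the merging group, plus
    Friedel mates) of each merged index receives the merged intensity.
    Returns the expanded set and the count of negative intensities
    clipped to zero.
    """
    if obs.symmetry is None:
        raise ValueError("observed set carries no merging symmetry")
    n_clipped = int(np.sum(obs.I < 0))
    I = np.clip(obs.I, 0.0, None)
    rots = obs.symmetry.rotation_parts()
    out: dict[tuple, float] = {}
    for W in rots:
        op = RationalSymOp(W)
        mapped = friedel_canonical(op.apply_to_miller(obs.hkl))
        for h, val in zip(map(tuple, mapped), I):
            out[h] = val
    hkl = np.array(sorted(out), dtype=np.int64)
    vals = np.array([out[tuple(h)] for h in hkl])
    p1 = SpaceGroupDef.from_symbol("P1")
    return ReflectionSet(obs.cell, p1, hkl, vals), n_clipped


def merge_under_group(p1: ReflectionSet, G: SpaceGroupDef) -> ReflectionSet:
    """Merge P1 intensities under the rotation parts of G (mean per orbit)."""
    rots = [RationalSymOp(W) for W in G.rotation_parts()]
    n = p1.n_reflections
    orbit_rep = np.array([tuple(h) for h in p1.hkl], dtype=np.int64)
    for op in rots:
        mapped = friedel_canonical(op.apply_to_miller(p1.hkl))
        smaller = _lex_less(mapped, orbit_rep)
        orbit_rep[smaller] = mapped[smaller]
    sums: dict[tuple, list] = {}
    for rep, val in zip(map(tuple, orbit_rep), p1.I):
        acc = sums.setdefault(rep, [0.0, 0])
        acc[0] += val
        acc[1] += 1
    hkl = np.array(sorted(sums), dtype=np.int64)
    vals = np.array([sums[tuple(h)][0] / sums[tuple(h)][1] for h in hkl])
    return ReflectionSet(p1.cell, G, hkl, vals)


def _lex_less(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    lt0 = a[:, 0] < b[:, 0]
    eq0 = a[:, 0] == b[:, 0]
    lt1 = a[:, 1] < b[:, 1]
    eq1 = a[:, 1] == b[:, 1]
    lt2 = a[:, 2] < b[:, 2]
    return lt0 | (eq0 & lt1) | (eq0 & eq1 & lt2)


def r_symop(I_p1: ReflectionSet, op: RationalSymOp) -> tuple[float, int]:
    """Symmetry-operator reliability for W (Eq. form above).

    Pairs (H, H W) with both members present are scored; W-invariant
    (self-paired) indices and pairs with a missing partner are skipped.
    Returns (R, number of scored pairs).  Raises :class:`NoPairsError`
    when nothing is scorable.
    """
    mapped = op.apply_to_miller(I_p1.hkl)
    canon = friedel_canonical(mapped)
    idx, found = I_p1.lookup(canon)
    self_paired = np.all(canon == I_p1.hkl, axis=1)
    use = found & ~self_paired
    if not np.any(use):
        raise NoPairsError(f"operator {op.triplet()} relates no reflection pairs")
    I1 = I_p1.I[use]
    I2 = I_p1.I[idx[use]]
    num = float(np.sum(np.abs(I1 - I2)))
    den = float(np.sum(I1 + I2))
    if den == 0:
        raise NoPairsError("all paired intensities are zero")
    # each unordered pair appears twice in the ordered sweep
    return num / den, int(np.sum(use)) // 2


def score_patterson_settings(
    I_p1: ReflectionSet,
    settings: list[PattersonSetting],
    r_max: float = 0.25,
    obs_p1: ReflectionSet | None = None,
) -> list[PattersonSetting]:
    """Fill worst-case R_symop per setting and flag plausibility.

    Operators are evaluated in the frame of ``I_p1`` (the reduced frame);
    the trivial setting scores 0 and is always plausible.  When an
    observed P1 set is supplied its worst-case score is filled as well
    and must also pass ``r_max`` for the setting to stay plausible.
    """
    out = []
    for s in settings:
        worst_calc = 0.0
        worst_obs = 0.0 if obs_p1 is not None else None
        for g in s.rotational_operators:
            if g.is_identity:
                continue
            r, _ = r_symop(I_p1, g)
            worst_calc = max(worst_calc, r)
            if obs_p1 is not None:
                ro, _ = r_symop(obs_p1, g)
                worst_obs = max(worst_obs, ro)
        plausible = worst_calc <= r_max and (worst_obs is None or worst_obs <= r_max)
        out.append(replace(
            s, max_rsymop_calc=worst_calc, max_rsymop_obs=worst_obs,
            plausible=plausible,
        ))
    return out
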