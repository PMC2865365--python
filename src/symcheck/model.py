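"""Coordinate model containers.

A :class:`CrystalModel` is a unit cell, a space group and an ordered list
of polypeptide chains holding C-alpha sites in fractional coordinates.
Chain order follows the source file; several downstream rules (choice of
the primary ASU model) depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lattice_symmetry import UnitCell
from .symmetry_core import ChangeOfBasisOp, RationalSymOp, SpaceGroupDef

__all__ = ["Chain", "CrystalModel", "ScattererModel"]


@dataclass
class Chain:
    """One polypeptide chain: id, one-letter sequence, C-alpha fractionals."""

    chain_id: str
    seq: str
    frac: np.ndarray  # (N, 3)

    def __post_init__(self):
        self.frac = np.atleast_2d(np.asarray(self.frac, dtype=float))
        if self.frac.shape[1] != 3:
            raise ValueError("fractional coordinates must be (N, 3)")
        if not np.all(np.isfinite(self.frac)):
            raise ValueError(f"non-finite coordinates in chain {self.chain_id}")

    @property
    def n_calpha(self) -> int:
        return len(self.frac)

    def transformed(self, op: RationalSymOp) -> "Chain":
        return Chain(self.chain_id, self.seq, op.apply(self.frac))


@dataclass
class ScattererModel:
    """Point-scatterer model for structure-factor synthesis.

    Unit scattering weights with optional isotropic B damping; every
    statistic downstream is invariant to the per-atom form factor, so
    nothing more elaborate is needed.
    """

    cell: UnitCell
    sites: np.ndarray                     # (N, 3) fractional
    occupancy: np.ndarray | None = None   # in (0, 1]
    b_iso: np.ndarray | None = None       # Angstrom^2, >= 0
    weight: np.ndarray | None = None

    def __post_init__(self):
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        n = len(self.sites)
        if n == 0:
            raise ValueError("empty scatterer model")
        if self.occupancy is None:
            self.occupancy = np.ones(n)
        if self.b_iso is None:
            self.b_iso = np.zeros(n)
        if self.weight is None:
            self.weight = np.ones(n)
        if np.any(self.occupancy <= 0) or np.any(self.occupancy > 1):
            raise ValueError("occupancies must lie in (0, 1]")
        if np.any(self.b_iso < 0):
            raise ValueError("B factors must be >= 0")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def shifted(self, x) -> "ScattererModel":
        return ScattererModel(
            self.cell, self.sites + np.asarray(x, dtype=float),
            self.occupancy, self.b_iso, self.weight,
        )


@dataclass
class CrystalModel:
    cell: UnitCell
    group: SpaceGroupDef
    chains: list[Chain]
    source: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_calpha(self) -> int:
        return sum(ch.n_calpha for ch in self.chains)

    def all_frac(self) -> np.ndarray:
        return np.concatenate([ch.frac for ch in self.chains], axis=0)

    def change_basis(self, cb: ChangeOfBasisOp) -> "CrystalModel":
        chains = [
            Chain(ch.chain_id, ch.seq, cb.apply_to_coords(ch.frac))
            for ch in self.chains
        ]
        return CrystalModel(
            self.cell.changed_basis(cb), self.group.transformed(cb),
            chains, self.source, list(self.warnings),
        )

    def with_cell(self, cell: UnitCell) -> "CrystalModel":
        return replace(self, cell=cell)

    def shifted(self, x) -> "CrystalModel":
        x = np.asarray(x, dtype=float)
        chains = [Chain(ch.chain_id, ch.seq, ch.frac + x) for ch in self.chains]
        return replace(self, chains=chains)

    def expand_to_p1(self) -> "CrystalModel":
        """Apply every group operator; chains gain an operator suffix."""
        p1 = SpaceGroupDef.from_symbol("P1")
        chains = []
        for i, op in enumerate(self.group.operators):
            for ch in self.chains:
                cid = ch.chain_id if op.is_identity and self.group.order == 1 \
                    else f"{ch.chain_id}.{i}"
                chains.append(Chain(cid, ch.seq, op.apply(ch.frac)))
        return CrystalModel(self.cell, p1, chains, self.source, list(self.warnings))

    def to_scatterers(self, b_iso: float = 0.0) -> ScattererModel:
        sites = self.all_frac()
        return ScattererModel(self.cell, sites, b_iso=np.full(len(sites), b_iso))
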