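"""Readers and writers: PDB coordinates, reflection files, reports.

Coordinate input is restricted to what the analysis needs: CRYST1 cell
and space group, protein chains, C-alpha atoms.  Solvent, ligands,
covalent modifications and alternate conformations (other than blank or
'A') are dropped with counts recorded in the model's warnings.
"""

from __future__ import annotations

import json
import math
import os
import re
from pathlib import Path

import gemmi
import numpy as np

from .intensities import ReflectionSet, friedel_canonical
from .lattice_symmetry import UnitCell
from .model import Chain, CrystalModel
from .model_symmetry import ASUModelSet, SymmetryReport
from .symmetry_core import RationalSymOp, SpaceGroupDef

__all__ = ["read_model", "write_model", "read_reflections", "write_outputs"]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "MSE": "M", "PHE": "F",
    "PRO": "P", "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
    "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}


def read_model(path) -> CrystalModel:
    """Parse a PDB file into a C-alpha CrystalModel.

    Requires a CRYST1 record with a Sohncke space-group symbol and at
    least one protein chain with C-alpha atoms.
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    cell = st.cell
    if not cell.is_crystal() or (cell.a == 1 and cell.b == 1 and cell.c == 1):
        raise ValueError(f"{path}: missing or placeholder CRYST1 record")
    ucell = UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    symbol = st.spacegroup_hm.strip()
    if not symbol:
        raise ValueError(f"{path}: CRYST1 carries no space-group symbol")
    group = SpaceGroupDef.from_symbol(symbol)  # raises for non-Sohncke
    warnings: list[str] = []
    n_altloc_dropped = 0
    n_het_dropped = 0
    chains: list[Chain] = []
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    for chain in st[0]:
        seq = []
        coords = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if not is_aa:
                if res.het_flag == "H" or res.is_water():
                    n_het_dropped += 1
                continue
            ca = None
            for atom in res:
                if atom.name != "CA":
                    continue
                if atom.altloc not in ("", "A", "\x00"):
                    n_altloc_dropped += 1
                    continue
                ca = atom
                break
            if ca is None:
                continue
            seq.append(_THREE_TO_ONE.get(res.name, "X"))
            coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        if coords:
            frac = ucell.fractionalize(np.array(coords))
            chains.append(Chain(chain.name, "".join(seq), frac))
    if not chains:
        raise ValueError(f"{path}: no protein chains with C-alpha atoms")
    if n_altloc_dropped:
        warnings.append(f"dropped {n_altloc_dropped} non-A altloc atoms")
    if n_het_dropped:
        warnings.append(f"dropped {n_het_dropped} non-protein residues")
    return CrystalModel(ucell, group, chains, source=str(path), warnings=warnings)


def _chain_letters(n: int):
    pool = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    return [pool[i % len(pool)] for i in range(n)]


def write_model(model: CrystalModel, path) -> None:
    """Write a C-alpha model as a PDB file (CRYST1 + ATOM/TER records).

    Fractional coordinates are canonicalized per chain (integer shift of
    the centroid into [0,1)) so chains are not torn across cell edges.
    """
    cell = model.cell
    symbol = model.group.symbol
    lines = [
        "CRYST1%9.3f%9.3f%9.3f%7.2f%7.2f%7.2f %-11s%4d"
        % (*cell.parameters, symbol, 1)
    ]
    serial = 1
    letters = _chain_letters(model.n_chains)
    for ch, letter in zip(model.chains, letters):
        cid = ch.chain_id if len(ch.chain_id) == 1 else letter
        frac = ch.frac - np.floor(ch.frac.mean(axis=0))
        cart = cell.orthogonalize(frac)
        for i, (xyz, aa) in enumerate(zip(cart, ch.seq or "A" * len(frac))):
            res3 = _ONE_TO_THREE.get(aa, "ALA")
            lines.append(
                "ATOM  %5d  CA  %3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f"
                "           C"
                % (serial, res3, cid, i + 1, xyz[0], xyz[1], xyz[2], 1.0, 0.0)
            )
            serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_reflections(path, cell: UnitCell, group: SpaceGroupDef) -> ReflectionSet:
    """Read merged reflections: mmCIF ``_refln`` loop or plain text.

    Plain text is whitespace-separated ``h k l I [sigI]``.  Amplitudes
    (F columns) are squared to intensities; an mmCIF cell, if present,
    must agree with the model cell within 1%.  Duplicate
    symmetry-equivalent indices are an error.
    """
    text = Path(path).read_text()
    if "_refln" in text and "loop_" in text:
        hkl, I, sig = _read_refln_cif(str(path), cell)
    else:
        hkl, I, sig = _read_hkl_text(text, path)
    _check_duplicates(np.array(hkl, dtype=np.int64), group, path)
    return ReflectionSet(
        cell, group, np.array(hkl, dtype=np.int64), np.array(I),
        sigI=None if sig is None else np.array(sig),
    )


def _read_hkl_text(text: str, path):
    hkl, I, sig = [], [], []
    has_sig = None
    bad: list[int] = []
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            h, k, l = (int(p) for p in parts[:3])
            inten = float(parts[3])
            s = float(parts[4]) if len(parts) > 4 else None
        except (ValueError, IndexError):
            bad.append(ln)
            continue
        hkl.append((h, k, l))
        I.append(inten)
        sig.append(s)
        has_sig = s is not None if has_sig is None else (has_sig and s is not None)
    if bad:
        raise ValueError(f"{path}: unparseable reflection lines: {bad}")
    if not hkl:
        raise ValueError(f"{path}: no reflections found")
    return hkl, I, (sig if has_sig else None)


def _read_refln_cif(path: str, cell: UnitCell):
    doc = gemmi.cif.read(path)
    block = doc.sole_block()
    cpar = [block.find_value(f"_cell.length_{x}") or
            block.find_value(f"_cell_length_{x}") for x in "abc"]
    if all(cpar):
        file_lengths = [float(gemmi.cif.as_number(v)) for v in cpar]
        model_lengths = [cell.a, cell.b, cell.c]
        for fv, mv in zip(file_lengths, model_lengths):
            if abs(fv - mv) > 0.01 * mv:
                raise ValueError(
                    f"{path}: cell in reflection file ({file_lengths}) "
                    f"differs from model cell by more than 1%"
                )
    names = ["index_h", "index_k", "index_l"]
    hloop = block.find("_refln.", names) or block.find("_refln_", names)
    if not hloop:
        raise ValueError(f"{path}: no _refln loop with h,k,l found")
    hkl = [tuple(int(hloop[i][j]) for j in range(3)) for i in range(len(hloop))]
    # intensity preferred over amplitude
    for tag, square in (("intensity_meas", False), ("F_meas_au", True),
                        ("F_meas", True)):
        col = block.find_values(f"_refln.{tag}") or block.find_values(f"_refln_{tag}")
        if col and len(col) == len(hkl):
            vals = [gemmi.cif.as_number(v) for v in col]
            I = [v * v if square else v for v in vals]
            return hkl, I, None
    raise ValueError(f"{path}: no intensity or amplitude column in _refln loop")


def _check_duplicates(hkl: np.ndarray, group: SpaceGroupDef, path) -> None:
    seen: dict[tuple, int] = {}
    rots = [RationalSymOp(W) for W in group.rotation_parts()]
    canon = friedel_canonical(hkl)
    for op in rots:
        mapped = friedel_canonical(op.apply_to_miller(hkl))
        from .intensities import _lex_less

        smaller = _lex_less(mapped, canon)
        canon[smaller] = mapped[smaller]
    for i, rep in enumerate(map(tuple, canon)):
        if rep in seen:
            raise ValueError(
                f"{path}: records {seen[rep] + 1} and {i + 1} are "
                f"symmetry-equivalent under {group.symbol} (orbit {rep})"
            )
        seen[rep] = i


def write_outputs(report: SymmetryReport, asu_models: ASUModelSet | None, out_dir) -> list[str]:
    """Write report.json, report.txt and one PDB per ASU model."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    jpath = out / "report.json"
    jpath.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n")
    written.append(str(jpath))
    tpath = out / "report.txt"
    tpath.write_text(format_report_text(report))
    written.append(str(tpath))
    if asu_models is not None:
        for i, m in enumerate(asu_models.models):
            p = out / f"model_coset_{i + 1}.pdb"
            write_model(m, p)
            written.append(str(p))
    return written


def format_report_text(report: SymmetryReport) -> str:
    def fmt(v, pct=False):
        if v is None:
            return "-"
        return f"{100 * v:.1f}" if pct else f"{v:.4f}"

    rows = [
        ("Input symmetry", report.input_group),
        ("Target symmetry", report.target_group),
        ("Patterson symmetry", report.patterson_symbol),
        ("No. of cosets", str(report.n_cosets)),
        ("Origin shift", "(%.5f, %.5f, %.5f)" % tuple(report.x_refined)),
        ("Correlation peak r", fmt(report.r_max)),
        ("Maximum Phi(g_i)", fmt(report.max_phi)),
        ("Delta r_sym (A)", fmt(report.delta_r_sym)),
        ("Delta r_ASU (A)", fmt(report.delta_r_asu)),
        ("Delta r_chain (A)", fmt(report.delta_r_chain)),
        ("Max R_symop I_calc (%)", fmt(report.rsymop_calc_max, pct=True)),
        ("Max R_symop I_obs (%)", fmt(report.rsymop_obs_max, pct=True)),
        ("Max Le Page delta (deg)", fmt(report.max_delta_deg)),
        ("Candidate", "yes" if report.candidate else "no"),
    ]
    width = max(len(k) for k, _ in rows)
    lines = [f"{k:<{width}}  {v}" for k, v in rows]
    for note in report.notes:
        lines.append(f"note: {note}")
    return "\n".join(lines) + "\n"
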