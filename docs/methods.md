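# Methods and numerical choices

## Model and assumptions

- Coordinate models are reduced to **Cα traces**: every statistic in
  the package (R_symop, correlation map, Φ, Δr) is either invariant to
  the per-atom form factor or defined directly on Cα positions, so side
  chains, solvent and ligands are dropped on input.
- Structure factors use **unit point scatterers** with optional
  isotropic B damping: `F(H) = Σ_j w_j occ_j exp(−B_j s²/4)
  exp(2πi H·x_j)`. Intensity-ratio statistics are unchanged by any
  common per-atom scattering factor.
- Only the **65 Sohncke space groups** are considered (chiral
  macromolecules exclude mirrors and inversions). Friedel mates are
  treated as equivalent everywhere.
- Symmetry algebra is **exact**: operators are 3×3 rational matrices
  with rational translations (denominators dividing 24), so group
  closure, coset decomposition and change-of-basis conjugation carry no
  floating-point error. `gemmi` supplies the space-group tables, the
  Gruber/Niggli cell reduction and PDB/mmCIF parsing; everything layered
  on top (closure, cosets, Patterson-setting enumeration, scoring) is
  implemented here.

## Pipeline stages and defaults

| Parameter | Default | Role |
|---|---|---|
| `d_min` | 3.5 Å | resolution limit for all intensity scores; fine enough to separate operators, coarse enough to stay fast |
| `delta_tol` | 1.4° | Le Page δ tolerance when hunting lattice twofolds; lattices within ~1° of a higher metric symmetry are still found |
| `rsymop_max` | 0.25 | worst-case R_symop for a Patterson setting to stay plausible; true operators under realistic noise stay well below this, unrelated pairings sit near 0.5 |
| `dr_sym_max` | 0.325 Å | Δr_sym cutoff for the candidate verdict (a conventional, deliberately arbitrary default) |
| `r_corr_min` | 0.8 | correlation-peak threshold in the space-group ranking; groups below it stay in the output with a reason code rather than vanishing |
| `match_tol` | 2.0 Å | mean Cα deviation allowed when matching chains under a trial operator |

Reference-frame chain: centring removal → Niggli reduction → P1
expansion → Patterson-setting enumeration (closure of subsets of the
found twofolds, classified into conventional frames and idealized
cells) → per-setting work in the conventional frame. Settings are
tried highest rotation order first; observed intensities, when given,
are advisory (they add a gate, their absence never blocks the verdict).

## Key statistics

- **R_symop(W)** = Σ|I_H − I_{HW}| / Σ(I_H + I_{HW}) over pairs with
  both members present; self-paired (W-invariant) indices are skipped.
  Exactly 0 when W is a symmetry of the intensity-generating model.
- **Correlation map r(x, G)**: Pearson correlation, over Miller
  indices, between the model's P1 intensities merged under G and the
  intensities of the ensemble of all G-copies of the model shifted
  by x. Evaluated on a grid of spacing ~d_min/2 by accumulating the
  pair (|S|²) and quadruple (|S|⁴) interference terms of the ensemble
  intensity on the reciprocal grid and inverse-FFTing — algebraically
  identical to direct per-grid-point evaluation (the test oracle) to
  ~1e−13. The grid peak is then polished off-grid by Nelder–Mead on
  the directly-evaluated correlation; components along polar axes of G
  (directions every rotation fixes) are zeroed by convention.
- **Φ(g)** = Σ|F_H|² |wrap(φ_H − φ_{HW} − 2πH·w)| / ((π/n) Σ|F_H|²)
  with n = 1: phase differences are wrapped into (−π, π], and the
  normalization makes Φ = 0 for an exactly invariant model and ≈ 0.5
  for an unrelated pairing. The modular order n is configurable but the
  plain n = 1 form is the default and the tested one.
- **Origin refinement** minimizes f(x) = Σ |O[(W_g − W_h)x + c]|² over
  matched Cα pairs — quadratic in x, solved by normal equations; the
  minimum-norm solution pins polar (null-space) components to 0.
  Δr_sym = √(f_min / N_pairs).
- **Δr_ASU / Δr_chain**: the n coset models of the higher-symmetry ASU
  are superposed (Kearsley quaternion method, oracle-checked against
  SVD/Kabsch) as whole ASUs or chain-by-chain; the residual RMS
  separates per-atom scatter (Δr_sym ≈ Δr_ASU) from rigid-body
  pseudosymmetry (Δr_sym ≫ Δr_ASU).

## Known gap: screw counterparts in the correlation map

The Pearson form of r(x, G) cannot reach ≈ 1.0 for the screw
counterpart of a true rotation group. If the model is invariant under
the rotation (e.g. P4) and G is the screw variant (P4₂), half the
ensemble reflections acquire the factor (1 + e^{iπl}) and are
extinguished, while the merged intensities are not; the correlation is
then mathematically capped near 0.6 (measured 0.55–0.70 on fixtures).
The acceptance suite keeps the ≈ 1.0 assertion for this case
unweakened, so it fails by design and documents the gap. The practical
consequence is benign: rotation/screw discrimination is carried by Φ
(contrast > 30×), and the true group's own peak does reach 1.0.
Alternatives considered (excluding extinct reflections from the
ensemble; amplitude rather than intensity averaging in the merge) break
the score's ability to *reject* wrong screw assignments and were not
adopted.

## Synthetic fixtures

`make_underassigned_structure` builds ground-truth crystals: chains are
self-avoiding Cα walks (3.8 Å steps, ≥ 4.0 Å non-consecutive
separation) placed clash-free among all symmetry copies; the default
cell is a generic metric symmetrized over the group's rotations (so it
has exactly the required metric symmetry, nothing more); the true-group
ASU is expanded by left-coset representatives into the presented
subgroup's ASU. Perturbations: independent per-atom Gaussian noise
(Δr_sym ≈ √6·σ), per-chain rigid rotations/shifts (pseudosymmetry
negatives), origin shifts (snapped to allowed origins for non-P1
presentations) and random unimodular basis scrambles (P1 only, where
the symbol stays valid). The generator emulates coordinate geometry
and merged intensity data; it does **not** emulate secondary structure,
side chains, bulk solvent, anisotropy or twinning.

Problem sizes throughout (chain lengths 8–50 residues, cells 40–60 Å,
d_min 3.5 Å, grids ≤ ~30³) are the package's own choices, set so the
full test suite runs in minutes while every statistic operates far from
its small-sample limits.

## Limitations

- Only rotational underassignment is detected; re-indexing ambiguity
  resolution, re-refinement and deposition-format output are out of
  scope.
- Chain matching requires equal-length chains at ≥ 95% sequence
  identity; engineered heterogeneity across copies defeats it (and is
  reported as a matching failure, not silently ignored).
- Merohedral twinning can mimic the intensity signatures scored here
  and is not modelled.
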