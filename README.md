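# porescale

Finite-size hydropathic scaling analysis of ion-channel pores.

Voltage-gated sodium channels conduct ions through a central pore whose
behaviour is set by the interplay of geometry (how narrow the pore is at
each depth) and hydropathicity (how hydrophobic or hydrophilic the
surrounding atoms are).  `porescale` asks how *cumulative* hydropathic
properties of the atomic environment change with the size of the
neighbourhood considered — from the first shell of pore-lining atoms out
to the whole tetramer — and whether that change is scale-invariant, the
signature of non-extensive, long-range interactions.

It is a library for structural bioinformaticians working with protonated
channel structures (any PDB file with hydrogens), with a synthetic-fixture
generator so every stage can be exercised and validated without any
structure download, plus a thin CLI.

## The method

For a pore point **p** on the principal pore axis (structure centered on
its mass center, long axis aligned with z):

* **Geometry** — pore radius `R(p) = min_i(‖c_i − p‖ − vdW_i)`, nearest
  atom distance `D(p) = min_i ‖c_i − p‖`, outer-surface radius
  `L(p) = max_i(‖c_i − p‖ + vdW_i)`.
* **Nested sampling** — spheres `l_α = D + α·(L−D)/K_α`, α = 1..K_α,
  with cumulative atom counts `N(p, l_α)`.
* **Atom packing** — the normalized count trace is fitted with four
  reparametrised sigmoid growth models (logistic, Gompertz, modified
  Gompertz, Richards), selected by AIC with case-resampling bootstrap
  intervals.  Parameters: asymptote `A`, maximum packing rate `t` (slope
  at the inflection scale `ξ`), lag end `s`, Richards shape `q̃` (related
  to the non-extensive entropic index by `q = 1 − q̃`).  The tangent at ξ
  crosses 0 at `s` and the asymptote at `o = s + A/t`, so `t = A/(o−s)`.
* **Hydropathic dipole field** — `h(p, l_α) = Σ HI_i·(c_i − p)` over atoms
  within `l_α`, with per-atom Kapcha–Rossky-style hydropathic indices
  (±0.5) plus weak Gaussian noise (σ = 0.001).  For a rotationally
  symmetric channel the radial part `‖h_xy‖` cancels and the field is its
  signed axial component `h_z` (kcal·Å/mol).
* **Scale invariance** — the hydropathic imbalance `I = ‖h_z‖/N` is fitted
  with power laws `I ∝ x^γ` separately below and above ξ (windows
  `(s, ξ]` and `(ξ, ·]`, in index or physical-scale space).  High Pearson
  coefficients in both phases mark a bi-phasic, scale-invariant pore
  region; `γ_pre > 0` and `γ_post < 0` quantify how the range of
  hydropathic interactions first grows, then contracts, with system size.
  The atom-packing energy `AE = ‖h_z‖/l_α` (kcal/mol) peaks in the window
  between the pore-domain/voltage-sensor crossover scale `ν` and `ξ`,
  an estimate of the PD–VSD coupling energy.

## Worked example

`examples/04_end_to_end_toy_channel.py` generates a ~6000-atom synthetic
channel whose radial packing follows a Richards curve and whose axial
dipole follows a planted bi-phasic power law, then recovers everything
with the full pipeline:

```
selected packing model: richards
  q_tilde      0.549   planted 0.54
  s            18.01   planted 18.02
  xi           20.38   planted 20.38
  gamma_pre     2.30   planted 2.27
  gamma_post   -4.36   planted -4.36
  Pearson      0.999 / -1.000  (pre/post quality)
  ||h_xy||/||h|| max: 5.79e-15 (4-fold symmetry cancels the radial field)
  nu           19.00   planted 19.00
  packing energy maximum in [nu, xi]: 24.5 kcal/mol at l = 20.3 A
```

The fitted `q̃ ≈ 0.55` says the packing sits between the Gompertz
(`q̃ → 0`) and logistic (`q̃ = 1`) limits; the exponent pair
(+2.3, −4.4) with |Pearson| ≈ 1 in both phases is the bi-phasic
scale-invariant regime, and the packing-energy maximum inside `[ν, ξ]`
estimates the coupling between the pore domains and the voltage sensors.

The other examples cover single capabilities: `01_pore_geometry.py`
(R/D/L/ν profiles along the axis), `02_packing_fit.py` (model selection,
bootstrap intervals, inflection geometry), `03_scale_invariance.py`
(detecting a planted scale-invariant region along the axis).

## Command line

```bash
porescale fixtures --out run/fx --seed 1          # synthetic channel + truth
porescale prepare  --pdb run/fx/toy_channel.pdb \
                   --segments run/fx/segments.yaml --out run/prep
porescale analyze  --pdb run/fx/toy_channel.pdb \
                   --segments run/fx/segments.yaml --out run/out \
                   --k-alpha 800 --pc-threshold 0.97
```

`analyze` writes `scaling_report.json` (per-point fits, exponents,
scale-invariant regions, crossover statistics) and `traces.tsv`; every
output embeds the config hash for provenance.  Real structures need a
segment map (chain / residue-range → S1–S6, P-helices, SF) such as the
bundled approximate NavAb map (`src/porescale/data/navab_segments.yaml`),
and must be protonated beforehand — atom counts differ across protonation
tools.

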