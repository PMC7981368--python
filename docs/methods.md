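# Methods

This note records the models the package implements, the numerical and
design choices behind them, what the synthetic generator does and does not
emulate, and the known limitations.

## Structure preparation

A structure is loaded from PDB (gemmi parser), waters and heteroatoms
excluded by default, highest-occupancy conformer kept for altLoc groups.
Protonation is an input requirement, not a feature: analyses weight every
atom, hydrogens included, and a structure without hydrogens is rejected
(`require_protonated=False` disables the check for toy inputs).  Atom
counts for the same crystal structure differ across protonation tools;
results should always be compared under one protonation protocol.

Centering and alignment: the molecular mass center is moved to the
origin and the *principal pore axis* — the eigenvector of the
mass-weighted inertia tensor with the smallest moment, i.e. the long axis
of the (roughly cylindrical) tetramer — is rotated onto z.  This is a
convention, not a steric path search: the axis is straight.  Eigenvector
signs are fixed deterministically (largest-magnitude component positive),
which makes the operation idempotent.  If the two smallest moments are
degenerate to 1e-9 (relative) the axis is ambiguous and an error is
raised; a user-supplied axis (`axis_override`) bypasses the inertia
analysis.  The extracellular→intracellular orientation of z cannot be
inferred from coordinates; `flip_z` resolves it, with the convention that
the selectivity-filter side sits at negative z.

Chemistry tables (van der Waals radii per element, masses, per-atom
hydropathic indices) ship as YAML package data and are overridable.
The hydropathicity table is a rule-based transcription of the binary
±0.5 atomic scale: N/O/P atoms, polar hydrogens and carbonyl /
carboxylate / amide / guanidinium carbons are hydrophilic (−0.5),
everything else hydrophobic (+0.5).  Per-atom noise χ ~ N(0, σ = 0.001)
is added once at load time (seeded, default seed 0); it guarantees a
non-degenerate dipole field on exactly symmetric structures while leaving
spatial behaviour untouched.

## Pore-axis sampling

Pore points sit on a uniform z-grid (default step 0.5 Å).  Without an
explicit range, the grid covers the open pore lumen: the contiguous band
around the structure's z midpoint where the pore radius R(p) is positive.
R may be negative at occluded points (closed activation gate); it is
reported, never clamped.

The pore-domain/voltage-sensor crossover scale ν(p) is, by default, the
distance from p to the nearest VSD-labelled atom center — the simplest
monotone geometric proxy for "where voltage-sensor structure begins."  An
alternative `fraction` mode returns the smallest distance at which VSD
atoms reach a given fraction of all sampled atoms.  Both need a segment
map (residue ranges → S1–S6/P-helix/SF labels), supplied as config; the
map is user responsibility and the bundled NavAb map is approximate.

Radial traces use K_α = 800 nested spheres by default, spanning
(D(p), L(p)].  Atoms exactly on a sphere boundary are counted inside
(θ(0) = 1), which makes the final count exactly the structure's atom
total.  All traces derive from one distance sort per pore point followed
by cumulative sums; property tests pin this to a per-sphere exhaustive
recount.

## Packing models and inflection geometry

Four reparametrised growth models are fitted to the max-normalized count
trace: logistic, Gompertz, modified Gompertz (a Gompertz core plus an
exponential second rise with parameters w, l_shift) and Richards, whose
shape parameter q̃ interpolates the family (q̃ = 1 logistic, q̃ → 0
Gompertz) and maps to the non-extensive entropic index as q = 1 − q̃.
Richards curves with |q̃| < 1e-6 are evaluated through the Gompertz limit;
all exponentials are clipped at ±700 for overflow safety; for q̃ < 0 the
curve is defined as 0 where its base becomes non-positive.

Inflection scales are closed-form — ξ = s + A/(2t) (logistic),
s + A/(e·t) (Gompertz), s + (1+q̃)/d (Richards, d = t/A·(1+q̃)^(1+1/q̃)) —
and numeric (second-derivative root after s) for the modified Gompertz.

The asymptote onset o uses the tangent construction: the tangent at ξ
crosses zero at the lag end s and reaches the asymptote A at o, giving
o = s + A/t exactly for the three plain sigmoids and making the maximum
packing rate identity t = A/(o − s) hold by construction.  A threshold
definition (smallest l with n ≥ 0.99·A, `o_mode="threshold"`) is kept as
an option; it inflates o − s by a model-dependent factor (≈1.65 for the
logistic) and breaks the identity, which is why it is not the default.

Fitting is multi-start trust-region least squares (starts: A₀ = max N,
s₀ = first l at 10% of max, t₀ = max finite-difference slope,
q̃₀ ∈ {0.2, 1, 2}; soft bounds A ∈ (0, 1.5], t > 0, s ∈ [0, max l],
q̃ ∈ (−0.99, 10]).  Degenerate traces (no sigmoid rise), optimizer
failure, or an inadmissible inflection produce a *flagged* fit with
diagnostics, never a silent failure.  Model selection minimises
AIC = n·ln(RSS/n) + 2k (small-sample AICc optional).  Uncertainty comes
from case-resampling bootstrap with percentile 95% intervals (default 100
replicates, seeded); replicates restart from the point estimate, failures
are dropped and a warning is emitted past 50%.

## Scaling analysis

The hydropathic imbalance I = ‖h_z‖/N is fitted by OLS in log-log space on
two windows — pre-inflection (s, ξ] and post-inflection (ξ, ·] — with the
Pearson coefficient of the same pairs grading each phase.  Two x-axes are
supported: the scaling index α and the physical scale l_α.  Because l_α
is affine, not proportional, in α, the two slopes genuinely differ; both
are computed (index space for aggregate-level comparisons, physical space
for the composite model below).  Non-positive I values in a window are
masked with a warning; fewer than 3 surviving points is an error.

The bi-phasic fits stop at the largest scale at which the atomic cluster
still grows (the farthest atom-center distance).  Between that scale and
the outer-surface radius L the counts and the field are frozen by
construction, and the flat tail would only dilute the post-inflection
slope.  For a full-size channel this tail is ~2% of the range; for
scaled-down synthetic fixtures it would otherwise bias γ_post noticeably.

Scale-invariant regions are maximal contiguous p_z intervals where
min(|PC_pre|, |PC_post|) ≥ 0.97 (configurable).  Cross-point aggregation
uses the per-α mean of max-normalized traces with 2.5/97.5 percentile
bands; domain-boundary markers ⟨α_s⟩, ⟨α_ξ⟩, ⟨α_ν⟩, ⟨α_o⟩ are means of
the per-point nearest indices.  This aggregation scheme is a package
choice (stated in output metadata) and aggregate-level numbers depend on
it.

The composite dipole model writes ‖h_z‖ ≈ C_phase · n_fit(l) · l^γ_phase
per phase, with the proportionality constants fitted on the log scale;
mean absolute relative errors are reported separately for the two phases
and for extrapolation into the lag domain, where the model is expected to
degrade (small-sample scales below s).  The packing energy AE = ‖h_z‖/l
maximised over the crossover window [ν, ξ] estimates the coupling energy
between the pore domains and the voltage sensors; the first/last-scale AE
values bound the energetics of the smallest and the complete cluster.
Rank agreement between the ξ(p) and ν(p) traces is summarised by their
mean absolute distance and Spearman correlations computed separately for
the two z-sign halves of the axis.

## Synthetic study conditions

The generator's defaults define the conditions every recovery study runs
under: a Richards packing curve with A = 1.05, t = 0.2 /Å, s = 18.02 Å,
q̃ = 0.54 (inflection near 20.4 Å); planted bi-phasic dipole exponents
γ_pre = +2.27 and γ_post = −4.36 with an "out"-oriented (negative) axial
field; 4-fold rotational symmetry; ~6000 atoms in 120 shells between 6
and 28 Å around a constriction ring at z = −10.

Construction: shell-wise cumulative counts follow the packing curve
(rounded to symmetry groups, so counts are exact at shell edges up to
group quantisation); group axial offsets are back-solved so the
HI-weighted axial sums reproduce the dipole target ‖h_z‖ = c·N(l)·l^γ at
every shell edge, with the exponent switching at ξ under amplitude
matching.  The global amplitude c is solved so no axial offset exceeds
half its shell radius — this both keeps the solve feasible and guarantees
the constriction ring stays the nearest structure to the axis.  Groups
alternate hydrophobic (C/H, +0.5) and hydrophilic (O, −0.5) so the net
hydropathy is ~0 and the dipole is essentially origin-independent, as in
a hydropathically balanced protein.  Hydrogen-like atoms (every 5th
group) satisfy the protonation check.  A dipole law that keeps changing
across atom-free shell gaps above the lag domain is unrealisable and
rejected.

What the fixtures do *not* emulate: real residue chemistry, sterics and
clash-free geometry, a realistic lag-domain dipole (the planted law below
the first populated shell is vacuous), an elongated tetramer inertia
profile (the toy is a thin slab, so it is emitted pre-aligned and is not
meant to exercise axis detection), or aggregate pseudo-symmetry along a
long pore axis.  Passing tests therefore validate the estimators and the
pipeline plumbing under the stated statistical structure — not the
biological claims about any particular channel.

Problem sizes in the shipped tests and acceptance script (chosen as
single-CPU defaults): 800 sampling spheres at the designated point, 200
for the 7-point axis scan; 50–100 simulation replicates for bias and
coverage studies on 400-point traces; 200 seeds for power-law recovery.

## Known limitations

* The straight principal axis ignores pore curvature; no HOLE-style path
  finding is attempted.
* The hydropathicity table is a rule-based binary scale; studies that
  need the exact published per-atom values should override the table.
* ν(p) uses atom centers; vdW-augmented or density-threshold variants
  would shift it by roughly an atomic radius.
* Aggregate-level quantities depend on the documented aggregation scheme;
  per-point quantities do not.
* The "in/out" dipole-field topology across scales is reduced to the
  signed h_z trace; topological pair analysis is out of scope.
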