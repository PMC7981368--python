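"""Full pipeline on a synthetic channel with planted ground truth.

Generates the default toy channel (Richards packing, bi-phasic dipole
exponents +2.27 / -4.36, 4-fold symmetry), runs the complete analysis at
the designated pore point, and compares every recovered quantity with the
planted value: packing parameters, inflection scale, scaling exponents,
radial-field cancellation, and the coupling-energy window between the
pore-domain/voltage-sensor crossover nu and the inflection scale xi.
"""

import tempfile
import warnings
from pathlib import Path

import porescale as ps

warnings.filterwarnings("ignore")

with tempfile.TemporaryDirectory() as tmp:
    spec = ps.FixtureSpec()                  # ~6000 atoms, seed 0
    info = ps.make_toy_channel(spec, Path(tmp) / "toy.pdb")
    st = ps.load_structure(info.path)
    st = ps.annotate_segments(st, info.segment_map)
    st.coords = info.structure.coords        # undo 1e-3 A PDB rounding

pa = ps.analyze_point(st, info.pore_point, ps.RunConfig(k_alpha=800))
fit, sf = pa.fit, pa.scaling_fit

print(f"selected packing model: {fit.model}")
print(f"  q_tilde    {fit.q_tilde:7.3f}   planted {spec.packing_params['q_tilde']}")
print(f"  s          {fit.s:7.2f}   planted {spec.packing_params['s']}")
print(f"  xi         {fit.xi:7.2f}   planted {info.xi:.2f}")
print(f"  gamma_pre  {sf.gamma_pre:7.2f}   planted {spec.gamma_pre}")
print(f"  gamma_post {sf.gamma_post:7.2f}   planted {spec.gamma_post}")
print(f"  Pearson    {sf.pc_pre:7.3f} / {sf.pc_post:.3f}  (pre/post quality)")

tr = ps.radial_traces(info.structure, info.pore_point, K_alpha=800,
                      noisy=False)
print(f"  ||h_xy||/||h|| max: {ps.radial_leakage_ratio(tr):.2e} "
      "(4-fold symmetry cancels the radial field)")

nu = ps.crossover_scale(st, info.pore_point)
ce = ps.coupling_energy(pa.traces.l, pa.traces.AE, nu, fit.xi)
print(f"  nu         {nu:7.2f}   planted {info.nu_true:.2f}")
print(f"  packing energy maximum in [nu, xi]: {ce['max_in_window']:.1f} "
      f"kcal/mol at l = {ce['l_at_max']:.1f} A")
print("\nThe imbalance I = |h_z|/N rises as l^gamma_pre below the "
      "inflection scale and decays as l^gamma_post above it: the planted "
      "scale-invariant, bi-phasic regime.")
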