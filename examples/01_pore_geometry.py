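"""Profile the pore axis of a synthetic channel: R(p), D(p), L(p), nu(p).

Builds a small toy channel, then walks the aligned pore axis and prints
the pore radius (distance to the nearest van der Waals surface), the
nearest atom-center distance, the outer-surface radius, and the distance
at which voltage-sensor structure begins (nu).  The pore radius is
smallest at the constriction ring the generator plants at z = -10.
"""

import tempfile
from pathlib import Path

import porescale as ps

with tempfile.TemporaryDirectory() as tmp:
    spec = ps.FixtureSpec(n_atoms=3000, seed=0)
    info = ps.make_toy_channel(spec, Path(tmp) / "toy.pdb")
    st = ps.load_structure(info.path)
    st = ps.annotate_segments(st, info.segment_map)

zc = spec.constriction_z
axis = ps.build_pore_points(st, z_step=1.0, z_range=(zc - 3, zc + 3),
                            with_nu=True)

print(f"{'p_z':>6} {'R':>7} {'D':>7} {'L':>7} {'nu':>7}   (Angstrom)")
for pt in axis.points:
    print(f"{pt.p[2]:6.1f} {pt.R:7.2f} {pt.D:7.2f} {pt.L:7.2f} {pt.nu:7.2f}")

R_min = min(pt.R for pt in axis.points)
z_min = next(pt.p[2] for pt in axis.points if pt.R == R_min)
print(f"\nnarrowest point: R = {R_min:.2f} A at p_z = {z_min:.1f} "
      "(the planted constriction)")
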