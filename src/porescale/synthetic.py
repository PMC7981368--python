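"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators cover the pipeline's input space without any download:

* :func:`make_packing_trace` — sigmoid count traces with optional noise,
  for the packing-model fitters.
* :func:`make_powerlaw_hiis` — power-law hydropathic-imbalance traces,
  for the log-log fitters.
* :func:`make_toy_channel` — a protonated-like, rotationally symmetric
  point-cloud "channel" written as a standard PDB file.  Atoms are placed
  in nested shells around a designated axis point so that the cumulative
  radial count follows a prescribed sigmoid, and axial offsets are
  back-solved shell by shell so that the axial hydropathic dipole follows
  the prescribed bi-phasic power law  h_z(l) = -c * N(l) * l**gamma  with
  an amplitude-matched exponent change at the packing inflection scale.
  Every planted atom is carbon- or hydrogen-like with hydropathic index
  +0.5 straight from the chemistry tables, so a reloaded fixture
  reproduces the planted dipole from chemistry lookups alone; the overall
  dipole amplitude c is solved so that no axial offset exceeds half its
  shell radius (which also pins the pore-radius minimum to the designated
  constriction ring).

Chemistry realism is not a goal; the statistical structure is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemistry import ChemistryTables
from .models import eval_model, inflection_point
from .structure import ChannelStructure

DEFAULT_PACKING = {"A": 1.05, "t": 0.2, "s": 18.02, "q_tilde": 0.54}


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of a synthetic toy channel.

    Defaults plant the working regime of the analysis: a Richards packing
    curve (A=1.05, t=0.2 1/Angstrom, s=18.02 Angstrom, q_tilde=0.54,
    inflection near 20.4 Angstrom), an outward-pointing dipole with
    pre/post-inflection exponents +2.27 / -4.36, four-fold rotational
    symmetry and ~6000 atoms.  ``l_max`` stays inside the active packing
    range so every shell keeps receiving atoms and the dipole increments
    remain realisable.
    """

    n_atoms: int = 6000
    symmetry: int = 4
    packing_model: str = "richards"
    packing_params: dict = field(default_factory=lambda: dict(DEFAULT_PACKING))
    gamma_pre: float = 2.27
    gamma_post: float = -4.36
    dipole_sign: int = -1          # -1 = "out" state (extracellular-facing)
    constriction_z: float = -10.0
    l_min: float = 6.0             # innermost planted shell radius, Angstrom
    l_max: float = 28.0            # outermost shell radius, Angstrom
    n_shells: int = 120
    vsd_start_radius: float = 19.0  # shells beyond -> voltage-sensor labels
    hydrogen_every: int = 5        # every k-th atom group is hydrogen-like
    seed: int = 0


@dataclass
class FixtureInfo:
    """Ground truth of a generated toy channel."""

    path: Path
    pore_point: np.ndarray
    spec: FixtureSpec
    xi: float
    s: float
    o: float
    nu_true: float                 # radius of the nearest VSD-labelled atom
    amplitude: float               # c in I(l) = c * l**gamma_pre
    n_atoms: int
    segment_map: list
    shell_edges: np.ndarray
    planted_h_z: np.ndarray        # dipole target at the shell edges
    planted_counts: np.ndarray     # cumulative atom count at the shell edges
    structure: ChannelStructure | None = None  # exact (unrounded) coordinates


def make_packing_trace(
    model: str,
    params: dict,
    noise_sd: float = 0.0,
    K_alpha: int = 200,
    seed: int = 0,
    l_range: tuple[float, float] | None = None,
    *,
    monotone: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid packing trace = model curve + iid Gaussian noise.

    Default ``l_range`` spans from zero to one inflection-domain length
    past the asymptote onset, covering lag, inflection and asymptote.
    """
    if l_range is None:
        A, t, s = params["A"], params["t"], params["s"]
        l_range = (0.0, s + 2.0 * A / t)
    l = np.linspace(l_range[0], l_range[1], K_alpha)
    n = eval_model(model, params, l)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        n = n + rng.normal(0.0, noise_sd, size=n.shape)
    if monotone:
        n = np.maximum.accumulate(n)
    return l, n


def make_powerlaw_hiis(
    gamma: float,
    beta: float,
    x_range: tuple[float, float],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Power-law imbalance trace I = exp(beta) * x**gamma * exp(eps)."""
    if x_range[0] <= 0:
        raise FixtureError("x_range must be positive")
    x = np.geomspace(x_range[0], x_range[1], n_points)
    eps = 0.0
    if noise_sd > 0:
        eps = np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    return x, np.exp(beta) * x**gamma * np.exp(eps)


def make_toy_channel(spec: FixtureSpec, path: str | Path) -> FixtureInfo:
    """Generate the toy channel PDB and return its ground truth.

    Construction: a constriction ring of 2*symmetry atoms at radius
    0.85*l_min fixes the pore-radius minimum at ``constriction_z``; then
    ``n_shells`` uniform shells between l_min and l_max receive
    symmetry-replicated atom groups until the cumulative count tracks the
    normalized packing curve.  Group axial offsets are solved per shell so
    the HI-weighted z sums reproduce that shell's dipole increment; shells
    that receive no atoms carry their (tiny) increment forward.
    """
    m = spec.symmetry
    if m < 2:
        raise FixtureError("symmetry must be >= 2 for radial-field cancellation")
    if spec.l_min <= 0 or spec.l_max <= spec.l_min:
        raise FixtureError("need 0 < l_min < l_max")
    rng = np.random.default_rng(spec.seed)
    params = spec.packing_params

    edges = np.linspace(spec.l_min, spec.l_max, spec.n_shells + 1)
    curve = eval_model(spec.packing_model, params, edges)
    if curve[-1] <= 0:
        raise FixtureError("packing curve non-positive at l_max")
    n_ring = 2 * m
    budget = spec.n_atoms - n_ring
    if budget < 4 * m:
        raise FixtureError("n_atoms too small for the requested symmetry")
    counts = np.floor(curve / curve[-1] * budget / m) * m
    counts = np.maximum.accumulate(counts)          # enforce monotone counts
    counts = counts - counts[0]
    if np.any(counts < 0):
        raise FixtureError("negative planted counts (check packing params)")

    cum = counts + n_ring
    xi = float(inflection_point(spec.packing_model, params,
                                (spec.l_min, spec.l_max)))
    gamma = np.where(edges <= xi, spec.gamma_pre, spec.gamma_post)
    amp_match = np.where(edges <= xi, 1.0,
                         xi ** (spec.gamma_pre - spec.gamma_post))
    raw_h = spec.dipole_sign * amp_match * cum * edges**gamma  # amplitude 1

    # pass 1: draw shell geometry, then find the largest dipole amplitude
    # for which every axial offset stays within half its shell radius
    shells = []
    carried = 0.0
    for k in range(spec.n_shells):
        n_groups = int(counts[k + 1] - counts[k]) // m
        target = float(raw_h[k + 1] - raw_h[k]) + carried
        if n_groups == 0:
            carried = target
            continue
        # an atom-free gap above the lag domain across which the dipole
        # target moved by a large fraction of its local magnitude means
        # the requested law cannot be realised there
        if (edges[k] > params["s"]
                and abs(carried) > 0.25 * max(abs(raw_h[k]), 1e-12)):
            raise FixtureError(
                "infeasible dipole tail: the packing curve leaves a long "
                "atom-free gap over which the requested dipole law must "
                "keep changing (reduce l_max or soften the exponents)"
            )
        carried = 0.0
        radii = np.sort(rng.uniform(edges[k] + 1e-3, edges[k + 1],
                                    size=n_groups))
        u = rng.uniform(0.3, 1.0, size=n_groups)
        denom = 0.5 * m * float(np.sum(u * radii))   # HI = +0.5 per atom
        shells.append({"k": k, "radii": radii, "u": u,
                       "kappa1": target / denom})
    if not shells:
        raise FixtureError("no atom-bearing shells (check packing params)")
    # beyond the last atom-bearing shell the dipole can no longer change;
    # the residual target out there must be negligible or the requested
    # exponents are unrealisable
    k_last = shells[-1]["k"]
    tail_resid = abs(raw_h[-1] - raw_h[k_last + 1])
    if tail_resid > 0.25 * max(abs(raw_h[k_last + 1]), 1e-12):
        raise FixtureError(
            "infeasible dipole tail: no atoms arrive in the outermost "
            "shells to carry the dipole increment (reduce l_max)"
        )
    max_kappa = max(abs(sh["kappa1"]) for sh in shells)
    if max_kappa <= 0:
        raise FixtureError("degenerate dipole target")
    amplitude = 0.4 / max_kappa

    # pass 2: place atoms
    zc = spec.constriction_z
    coords, elements, res_seqs, chains, names = [], [], [], [], []
    chain_ids = [chr(ord("A") + k) for k in range(min(m, 26))]

    def add_group(r, z_off, elem, res_seq):
        phi0 = rng.uniform(0, 2 * np.pi)
        rho = np.sqrt(max(r**2 - z_off**2, 1e-12))
        for k in range(m):
            phi = phi0 + 2 * np.pi * k / m
            coords.append((rho * np.cos(phi), rho * np.sin(phi), zc + z_off))
            elements.append(elem)
            res_seqs.append(res_seq)
            chains.append(chain_ids[k % len(chain_ids)])
            names.append("HX" if elem == "H" else "CX")

    res_counter = 1
    for elem in ("C", "O"):                 # constriction ring, z offset 0
        add_group(0.85 * spec.l_min, 0.0, elem, res_counter)
        res_counter += 1

    # Alternate hydrophobic (+0.5: C/H) and hydrophilic (-0.5: O) groups so
    # the net hydropathy stays near zero and the dipole field is (almost)
    # origin-independent, as for a hydropathically balanced protein.  A
    # hydrophilic group realises the same dipole increment with the axial
    # offset mirrored, so the shell targets are unaffected.
    group_index = 0
    vsd_first_res = None
    vsd_min_r = None
    for sh in shells:
        z_offs = amplitude * sh["kappa1"] * sh["u"] * sh["radii"]
        for r, z_off in zip(sh["radii"], z_offs):
            group_index += 1
            if group_index % 2 == 0:
                elem, z_off = "O", -z_off
            else:
                elem = "H" if group_index % spec.hydrogen_every == 0 else "C"
            if r >= spec.vsd_start_radius and vsd_first_res is None:
                vsd_first_res = res_counter
                vsd_min_r = float(r)
            add_group(float(r), float(z_off), elem, res_counter)
            res_counter += 1
    if vsd_first_res is None:
        vsd_first_res = res_counter
        vsd_min_r = float(edges[-1])

    path = Path(path)
    _write_fixture_pdb(path, coords, elements, names, res_seqs, chains)

    tables = ChemistryTables.default()
    element_arr = np.array(elements, dtype=object)
    name_arr = np.array(names, dtype=object)
    resname_arr = np.full(len(coords), "TOY", dtype=object)
    hi = np.array([tables.hi("TOY", an, el) for an, el in zip(names, elements)])
    exact = ChannelStructure(
        serial=np.arange(1, len(coords) + 1),
        element=element_arr, atom_name=name_arr, res_name=resname_arr,
        res_seq=np.array(res_seqs, dtype=int),
        chain=np.array(chains, dtype=object),
        coords=np.array(coords, dtype=float),
        mass=np.array([tables.mass(el) for el in elements]),
        vdw=np.array([tables.vdw(el) for el in elements]),
        hi=hi, hi_noisy=hi.copy(),
    )

    segment_map = [
        {"chain": "*", "res_start": 1, "res_end": vsd_first_res - 1,
         "segment": "S5"},
        {"chain": "*", "res_start": vsd_first_res, "res_end": res_counter,
         "segment": "S1"},
    ]
    s = float(params["s"])
    o = s + float(params["A"]) / float(params["t"])
    planted = amplitude * (raw_h - raw_h[0])
    return FixtureInfo(
        path=path, pore_point=np.array([0.0, 0.0, zc]), spec=spec,
        xi=xi, s=s, o=o, nu_true=float(vsd_min_r), amplitude=amplitude,
        n_atoms=len(coords), segment_map=segment_map, shell_edges=edges,
        planted_h_z=planted, planted_counts=cum, structure=exact,
    )


def _write_fixture_pdb(path, coords, elements, names, res_seqs, chains):
    with open(path, "w") as fh:
        for i, ((x, y, z), elem, name, seq, ch) in enumerate(
            zip(coords, elements, names, res_seqs, chains), start=1
        ):
            fh.write(
                f"ATOM  {i % 100000:>5d}  {name:<3s} TOY {ch:1s}"
                f"{seq % 10000:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.0:6.2f}{0.0:6.2f}          {elem:>2s}\n"
            )
        fh.write("END\n")
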