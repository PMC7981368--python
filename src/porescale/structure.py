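"""Channel-structure model: PDB loading, mass centering, pore-axis alignment,
and pore-domain / voltage-sensing-domain segment annotation.

A channel structure is a tetrameric (or arbitrary) atom collection held in
parallel numpy arrays.  After :func:`center_and_align` the molecular mass
center sits at the origin and the principal pore axis — the eigenvector of
the mass-weighted inertia tensor with the smallest moment, i.e. the long
axis of the assembly — coincides with the z-axis, so that pore points can be
sampled on a straight vertical line.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chemistry import ChemistryTables

#: segment label -> structural domain
SEGMENT_DOMAIN = {
    "S1": "VSD", "S2": "VSD", "S3": "VSD", "S4": "VSD", "S4S5_linker": "VSD",
    "S5": "PD", "P_helix": "PD", "SF": "PD", "P2_helix": "PD", "S6": "PD",
}

KNOWN_SEGMENTS = set(SEGMENT_DOMAIN) | {"other"}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureError(ValueError):
    pass


@dataclass
class Atom:
    """Single-atom view (a row of :class:`ChannelStructure`)."""

    serial: int
    element: str
    atom_name: str
    res_name: str
    res_seq: int
    chain: str
    coord: np.ndarray
    mass: float
    vdw: float
    hi: float
    hi_noisy: float
    segment: str = "other"
    domain: str = "other"


@dataclass
class ChannelStructure:
    """Atom collection with orientation metadata.

    Arrays are parallel over atoms and keep file order.  ``rotation`` is the
    cumulative rotation applied by :func:`center_and_align` (identity before).
    """

    serial: np.ndarray
    element: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    res_seq: np.ndarray
    chain: np.ndarray
    coords: np.ndarray
    mass: np.ndarray
    vdw: np.ndarray
    hi: np.ndarray
    hi_noisy: np.ndarray
    segment: np.ndarray = None  # type: ignore[assignment]
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    es_to_is: bool = True

    def __post_init__(self):
        if self.segment is None:
            self.segment = np.full(self.n_atoms, "other", dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    @property
    def mass_center(self) -> np.ndarray:
        return self.mass @ self.coords / self.total_mass

    @property
    def domain(self) -> np.ndarray:
        return np.array([SEGMENT_DOMAIN.get(s, "other") for s in self.segment],
                        dtype=object)

    def atom(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]), element=str(self.element[i]),
            atom_name=str(self.atom_name[i]), res_name=str(self.res_name[i]),
            res_seq=int(self.res_seq[i]), chain=str(self.chain[i]),
            coord=self.coords[i].copy(), mass=float(self.mass[i]),
            vdw=float(self.vdw[i]), hi=float(self.hi[i]),
            hi_noisy=float(self.hi_noisy[i]), segment=str(self.segment[i]),
            domain=SEGMENT_DOMAIN.get(str(self.segment[i]), "other"),
        )

    def copy(self) -> "ChannelStructure":
        return copy.deepcopy(self)


def load_structure(
    pdb_path: str | Path,
    tables: ChemistryTables | None = None,
    *,
    exclude_hetero: bool = True,
    exclude_waters: bool = True,
    require_protonated: bool = True,
    add_noise: bool = True,
    noise_sigma: float = 0.001,
    noise_seed: int = 0,
) -> ChannelStructure:
    """Parse a protonated PDB file and attach chemistry to every atom.

    Per-atom hydropathic indices receive additive Gaussian noise
    ``N(0, noise_sigma)`` (one draw per atom, seeded), which guarantees a
    non-degenerate hydropathic dipole field on exactly symmetric inputs
    while leaving its spatial behaviour untouched.  For altLoc groups only
    the highest-occupancy conformer is kept.
    """
    tables = tables or ChemistryTables.default()
    st = gemmi.read_pdb(str(pdb_path))
    if len(st) == 0:
        raise StructureError(f"no models in {pdb_path}")
    model = st[0]

    rows = []
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES and exclude_waters:
                continue
            if exclude_hetero and res.het_flag == "H" and res.name not in WATER_NAMES:
                continue
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for at in best.values():
                elem = at.element.name.upper()
                if elem in ("", "X"):
                    raise StructureError(
                        f"unknown element for atom serial {at.serial} "
                        f"({res.name} {at.name})"
                    )
                rows.append((
                    at.serial, elem, at.name, res.name, res.seqid.num,
                    chain.name, (at.pos.x, at.pos.y, at.pos.z),
                ))

    if not rows:
        raise StructureError(f"no atoms parsed from {pdb_path}")

    serial = np.array([r[0] for r in rows], dtype=int)
    element = np.array([r[1] for r in rows], dtype=object)
    atom_name = np.array([r[2] for r in rows], dtype=object)
    res_name = np.array([r[3] for r in rows], dtype=object)
    res_seq = np.array([r[4] for r in rows], dtype=int)
    chain_id = np.array([r[5] for r in rows], dtype=object)
    coords = np.array([r[6] for r in rows], dtype=float)

    if require_protonated and not np.any((element == "H") | (element == "D")):
        raise StructureError("structure appears unprotonated (no hydrogens found)")

    mass = np.array([tables.mass(e, s) for e, s in zip(element, serial)])
    vdw = np.array([tables.vdw(e, s) for e, s in zip(element, serial)])
    hi = np.array([
        tables.hi(rn, an, e, s)
        for rn, an, e, s in zip(res_name, atom_name, element, serial)
    ])
    if add_noise:
        rng = np.random.default_rng(noise_seed)
        hi_noisy = hi + rng.normal(0.0, noise_sigma, size=hi.shape)
    else:
        hi_noisy = hi.copy()

    return ChannelStructure(
        serial=serial, element=element, atom_name=atom_name, res_name=res_name,
        res_seq=res_seq, chain=chain_id, coords=coords, mass=mass, vdw=vdw,
        hi=hi, hi_noisy=hi_noisy,
    )


def inertia_tensor(coords: np.ndarray, mass: np.ndarray) -> np.ndarray:
    """Mass-weighted inertia tensor about the mass center."""
    com = mass @ coords / mass.sum()
    r = coords - com
    r2 = np.einsum("ij,ij->i", r, r)
    return float(mass @ r2) * np.eye(3) - np.einsum("i,ij,ik->jk", mass, r, r)


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip an eigenvector so its largest-magnitude component is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def center_and_align(
    structure: ChannelStructure,
    *,
    axis_override: np.ndarray | None = None,
    flip_z: bool = False,
    degeneracy_rtol: float = 1e-9,
) -> ChannelStructure:
    """Center the mass center on the origin and rotate the pore axis onto z.

    The pore axis is the inertia-tensor eigenvector with the smallest moment
    (the long axis); ``axis_override`` substitutes a user-supplied axis.
    ``flip_z`` reverses the z orientation (180-degree rotation about x) for
    structures whose extracellular side would otherwise point the wrong way;
    z is oriented extracellular -> intracellular by convention.
    """
    out = structure.copy()
    com = out.mass_center
    coords = out.coords - com

    if axis_override is not None:
        axis = np.asarray(axis_override, dtype=float)
        axis = axis / np.linalg.norm(axis)
    else:
        tensor = inertia_tensor(out.coords, out.mass)
        w, vecs = np.linalg.eigh(tensor)  # ascending moments
        scale = max(abs(w[2]), 1.0)
        if (w[1] - w[0]) <= degeneracy_rtol * scale:
            raise StructureError(
                "degenerate inertia tensor: principal pore axis is ambiguous"
            )
        axis = _canonical_sign(vecs[:, 0])

    # orthonormal right-handed basis (e1, e2, axis) -> (x, y, z)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(helper @ axis) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    rot = np.vstack([e1, e2, axis])
    if np.allclose(axis, [0.0, 0.0, 1.0], atol=1e-12):
        rot = np.eye(3)  # already aligned: avoid a spurious in-plane spin
    if flip_z:
        rot = np.diag([1.0, -1.0, -1.0]) @ rot

    out.coords = coords @ rot.T
    out.rotation = rot @ out.rotation
    return out


def load_segment_map(source) -> list[dict]:
    """Accept a YAML path, a mapping with key ``segments``, or a list of
    ``{chain, res_start, res_end, segment}`` entries."""
    if isinstance(source, (str, Path)):
        import yaml

        with open(source) as fh:
            source = yaml.safe_load(fh)
    if isinstance(source, dict):
        source = source.get("segments", [])
    entries = []
    for e in source:
        seg = e["segment"]
        if seg not in KNOWN_SEGMENTS:
            raise StructureError(f"unknown segment label {seg!r}")
        entries.append({
            "chain": str(e.get("chain", "*")),
            "res_start": int(e["res_start"]),
            "res_end": int(e["res_end"]),
            "segment": seg,
        })
    return entries


def annotate_segments(structure: ChannelStructure, segment_map) -> ChannelStructure:
    """Label every atom with its transmembrane segment and derived domain.

    Residues not covered by the map are labelled ``other``.  Entries whose
    chain selections intersect must not overlap in residue range.
    """
    entries = load_segment_map(segment_map)
    for i, a in enumerate(entries):
        if a["res_start"] > a["res_end"]:
            raise StructureError(f"inverted range in segment map entry {i}")
        for b in entries[i + 1:]:
            chains_meet = (a["chain"] == "*" or b["chain"] == "*"
                           or a["chain"] == b["chain"])
            if chains_meet and not (a["res_end"] < b["res_start"]
                                    or b["res_end"] < a["res_start"]):
                raise StructureError(
                    f"overlapping segment ranges: {a} vs {b}"
                )

    out = structure.copy()
    seg = np.full(out.n_atoms, "other", dtype=object)
    for e in entries:
        sel = (out.res_seq >= e["res_start"]) & (out.res_seq <= e["res_end"])
        if e["chain"] != "*":
            sel &= out.chain == e["chain"]
        seg[sel] = e["segment"]
    out.segment = seg
    return out


def write_pdb(structure: ChannelStructure, path: str | Path) -> None:
    """Write the structure as fixed-width ATOM records (8.3f coordinates)."""
    with open(path, "w") as fh:
        for i in range(structure.n_atoms):
            name = str(structure.atom_name[i])
            # column-13 alignment rule: 1/2-char element names start col 14
            pad = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = structure.coords[i]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
                "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
                "{b:6.2f}          {elem:>2s}\n".format(
                    serial=int(structure.serial[i]) % 100000, name=pad,
                    alt=" ", res=str(structure.res_name[i]),
                    chain=str(structure.chain[i])[:1] or "A",
                    seq=int(structure.res_seq[i]) % 10000, icode=" ",
                    x=x, y=y, z=z, occ=1.0, b=0.0,
                    elem=str(structure.element[i])[:2],
                )
            )
        fh.write("END\n")
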