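"""Shared fixtures: in-memory structures and the session toy channel."""

from __future__ import annotations

import numpy as np
import pytest

import porescale as ps
from porescale.structure import ChannelStructure


def build_structure(
    coords,
    *,
    hi=None,
    vdw=None,
    mass=None,
    element="C",
    segment=None,
    res_seq=None,
) -> ChannelStructure:
    """Assemble a ChannelStructure from raw arrays (test scaffolding)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    hi = np.full(n, 0.5) if hi is None else np.asarray(hi, dtype=float)
    vdw = np.full(n, 1.7) if vdw is None else np.asarray(vdw, dtype=float)
    mass = np.full(n, 12.0) if mass is None else np.asarray(mass, dtype=float)
    st = ChannelStructure(
        serial=np.arange(1, n + 1),
        element=np.full(n, element, dtype=object),
        atom_name=np.full(n, "CX", dtype=object),
        res_name=np.full(n, "TOY", dtype=object),
        res_seq=np.arange(1, n + 1) if res_seq is None else np.asarray(res_seq),
        chain=np.full(n, "A", dtype=object),
        coords=coords,
        mass=mass,
        vdw=vdw,
        hi=hi,
        hi_noisy=hi.copy(),
    )
    if segment is not None:
        st.segment = np.asarray(segment, dtype=object)
    return st


def random_structure(n: int, seed: int, box: float = 30.0) -> ChannelStructure:
    """Random atom cloud with mixed hydropathic indices and radii."""
    rng = np.random.default_rng(seed)
    st = build_structure(
        rng.uniform(-box, box, size=(n, 3)),
        hi=rng.choice([-0.5, 0.5], size=n),
        vdw=rng.uniform(1.0, 2.0, size=n),
        mass=rng.uniform(1.0, 16.0, size=n),
    )
    st.hi_noisy = st.hi + rng.normal(0, 0.001, size=n)
    return st


def elongated_tetramer(seed: int = 0, n_per_rod: int = 60) -> ChannelStructure:
    """Four parallel rods along z at radius 8: a long-axis-z point cloud."""
    rng = np.random.default_rng(seed)
    pts = []
    for k in range(4):
        phi = np.pi / 2 * k
        x0, y0 = 8 * np.cos(phi), 8 * np.sin(phi)
        z = np.linspace(-20, 20, n_per_rod)
        jitter = rng.normal(0, 0.5, size=(n_per_rod, 3))
        pts.append(np.column_stack([np.full(n_per_rod, x0),
                                    np.full(n_per_rod, y0), z]) + jitter)
    return build_structure(np.vstack(pts))


@pytest.fixture(scope="session")
def toy_info(tmp_path_factory):
    path = tmp_path_factory.mktemp("fixtures") / "toy_channel.pdb"
    return ps.make_toy_channel(ps.FixtureSpec(), path)


@pytest.fixture(scope="session")
def toy_structure(toy_info):
    return ps.annotate_segments(toy_info.structure, toy_info.segment_map)
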