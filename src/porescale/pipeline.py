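"""End-to-end orchestration: structure -> geometry -> traces -> fits -> report.

The per-point analysis chain is: nested-sphere traces, minimum-AIC sigmoid
packing fit, bi-phasic log-log fit of the hydropathic imbalance on the
pre-inflection window (s, xi] and the post-inflection window (xi, L].
The axis-level analysis aggregates per-point results into scale-invariant
regions, the inflection-vs-crossover correlation, and (at a representative
point of the best region) the composite CHDF model with its
coupling-energy window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import models, sampling, scaling
from .config import RunConfig
from .geometry import PoreAxisSet, PorePoint, build_pore_points
from .models import PackingFit
from .sampling import RadialTraces
from .scaling import ScalingFit
from .structure import ChannelStructure


@dataclass
class PointAnalysis:
    """Everything computed at one pore point."""

    point: PorePoint
    traces: RadialTraces
    fit: PackingFit | None
    scaling_fit: ScalingFit | None
    scaling_fit_alpha: ScalingFit | None
    error: str = ""


@dataclass
class AxisAnalysis:
    """Per-axis aggregation of the point analyses."""

    axis: PoreAxisSet
    points: list[PointAnalysis]
    regions: list[tuple[float, float]]
    crossover: dict | None
    aggregate_N: scaling.AggregateTrace | None
    aggregate_I: scaling.AggregateTrace | None


def analyze_point(
    structure: ChannelStructure,
    point: PorePoint | np.ndarray,
    config: RunConfig | None = None,
) -> PointAnalysis:
    """Run traces, packing fit and bi-phasic scaling fits at one point."""
    cfg = config or RunConfig()
    tr = sampling.radial_traces(structure, point, K_alpha=cfg.k_alpha,
                                noisy=cfg.add_noise)
    out = PointAnalysis(point=tr.p, traces=tr, fit=None, scaling_fit=None,
                        scaling_fit_alpha=None)
    try:
        fit = models.select_model(tr.l, tr.N, o_mode=cfg.o_mode,
                                  eps_asym=cfg.eps_asym, aicc=cfg.aicc)
    except models.ModelError as exc:
        out.error = str(exc)
        return out
    out.fit = fit
    if not fit.converged:
        out.error = fit.message
        return out
    if cfg.bootstrap:
        try:
            models.bootstrap_ci(tr.l, tr.N, fit, n_boot=cfg.n_boot,
                                seed=cfg.noise_seed)
        except models.ModelError:
            pass
    # Scales beyond the farthest atom center are frozen (N and h constant up
    # to the outer vdW surface L) and carry no scaling information; the
    # bi-phasic fits stop at the last cluster-growth scale.
    a_last = int(np.searchsorted(tr.N, tr.N[-1], side="left"))
    sl = slice(0, a_last + 1)
    I = tr.I  # nan where N == 0; the log-log fitter masks those
    try:
        out.scaling_fit = scaling.fit_biphasic(
            tr.l[sl], I[sl], fit.s, fit.xi, x_axis="physical_l")
    except scaling.ScalingError as exc:
        out.error = f"physical-l scaling fit failed: {exc}"
    try:
        # index-space fit: map the s/xi scales to their alpha indices
        alpha = tr.alpha.astype(float)
        a_s = 1 + int(np.argmin(np.abs(tr.l - fit.s)))
        a_xi = 1 + int(np.argmin(np.abs(tr.l - fit.xi)))
        if a_s < a_xi < a_last:
            out.scaling_fit_alpha = scaling.fit_biphasic(
                alpha[sl], I[sl], float(a_s), float(a_xi),
                x_axis="alpha_index")
    except scaling.ScalingError:
        pass
    return out


def analyze_axis(
    structure: ChannelStructure,
    config: RunConfig | None = None,
    axis: PoreAxisSet | None = None,
) -> AxisAnalysis:
    """Per-point analysis over the pore-axis grid plus axis-level statistics."""
    cfg = config or RunConfig()
    with_nu = bool(np.any(structure.domain == "VSD"))
    if axis is None:
        axis = build_pore_points(
            structure, z_step=cfg.z_step,
            z_range=tuple(cfg.z_range) if cfg.z_range else None,
            with_nu=with_nu, nu_mode=cfg.nu_mode)
    pts = [analyze_point(structure, pt, cfg) for pt in axis.points]

    z = axis.z
    which = "alpha_index" if cfg.x_axis == "alpha_index" else "physical_l"
    fits = [
        (p.scaling_fit_alpha if which == "alpha_index" else p.scaling_fit)
        for p in pts
    ]
    regions = scaling.detect_scale_invariance(z, fits, cfg.pc_threshold)

    crossover = None
    if with_nu:
        xi_tr = np.array([p.fit.xi if p.fit and p.fit.converged else np.nan
                          for p in pts])
        nu_tr = np.array([pt.nu if pt.nu is not None else np.nan
                          for pt in axis.points])
        crossover = scaling.crossover_correlation(z, xi_tr, nu_tr)

    boundaries = {}
    for i, p in enumerate(pts):
        if p.fit and p.fit.converged:
            boundaries[i] = {"s": p.fit.s, "xi": p.fit.xi, "o": p.fit.o,
                             "nu": axis.points[i].nu}
    traces = [p.traces for p in pts]
    agg_N = agg_I = None
    if traces:
        agg_N = scaling.aggregate_traces(traces, "N", boundaries)
        agg_I = scaling.aggregate_traces(traces, "I", boundaries)
    return AxisAnalysis(axis=axis, points=pts, regions=regions,
                        crossover=crossover, aggregate_N=agg_N,
                        aggregate_I=agg_I)


def point_report(pa: PointAnalysis) -> dict:
    d: dict = {"p_z": float(pa.point.p[2]), "R": pa.point.R, "D": pa.point.D,
               "L": pa.point.L, "nu": pa.point.nu, "error": pa.error}
    if pa.fit is not None:
        f = pa.fit
        d["fit"] = {
            "model": f.model, **{k: float(v) for k, v in f.params.items()},
            "q": f.q, "xi": f.xi, "o": f.o, "os": f.os_, "aic": f.aic,
            "mafe": f.mafe, "converged": f.converged, "ci": f.ci,
        }
    for key, sf in (("scaling_physical_l", pa.scaling_fit),
                    ("scaling_alpha_index", pa.scaling_fit_alpha)):
        if sf is not None:
            d[key] = dataclasses.asdict(sf)
    return d


def axis_report(ax: AxisAnalysis, config: RunConfig | None = None) -> dict:
    rep: dict = {
        "n_points": len(ax.points),
        "z_range": list(ax.axis.z_range),
        "z_step": ax.axis.z_step,
        "scale_invariant_regions": [list(r) for r in ax.regions],
        "crossover_correlation": ax.crossover,
        "points": [point_report(p) for p in ax.points],
    }
    for name, agg in (("aggregate_N", ax.aggregate_N),
                      ("aggregate_I", ax.aggregate_I)):
        if agg is not None:
            rep[name] = {
                "alpha_s": agg.alpha_s, "alpha_xi": agg.alpha_xi,
                "alpha_nu": agg.alpha_nu, "alpha_o": agg.alpha_o,
            }
    if config is not None:
        rep["provenance"] = config.provenance()
    return rep


def composite_at_point(pa: PointAnalysis) -> dict | None:
    """Composite CHDF model + coupling-energy window at one analyzed point."""
    if not (pa.fit and pa.fit.converged and pa.scaling_fit):
        return None
    tr = pa.traces
    comp = scaling.composite_chdf_model(pa.fit, pa.scaling_fit, tr.l, tr.h_z)
    out = {k: v for k, v in comp.items() if not isinstance(v, np.ndarray)}
    nu = pa.point.nu
    if nu is not None and nu < pa.fit.xi:
        out["coupling"] = scaling.coupling_energy(tr.l, tr.AE, nu, pa.fit.xi)
    return out
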