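"""Sigmoid atom-packing models: evaluation, fitting, model selection,
inflection analysis and bootstrap uncertainty.

The normalized cumulative atom count n(l) around a pore point is described
by reparametrised growth models whose parameters carry direct geometric
meaning: asymptote A, maximum packing rate t (the slope at the inflection
scale xi), and lag-domain end s (where the tangent at xi crosses zero).

    logistic          n = A / (1 + exp(4t/A*(s - l) + 2))
    gompertz          n = A * exp(-exp(e*t/A*(s - l) + 1))
    modified_gompertz gompertz + A*exp(w*(l - l_shift))   (second rise)
    richards          n = A * (1 + q*b*exp(-d*l))**(-1/q)
                      b = exp(1 + q + d*s),  d = t/A*(1+q)**(1+1/q)

(q denotes the Richards shape parameter q-tilde).  The logistic and
Gompertz curves are the q=1 and q->0 special cases of the Richards model.
The inflection scale has closed form for all but the modified Gompertz:

    logistic  xi = s + A/(2t)
    gompertz  xi = s + A/(e*t)
    richards  xi = s + (1+q)/d

The asymptote onset o is the scale where the tangent at xi reaches A; for
all three Zwietering-form models this gives o = s + A/t exactly, hence the
identity t = A/(o - s).  A threshold alternative (smallest l with
n >= (1-eps)*A) is available via ``o_mode="threshold"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

E = np.e

MODELS = ("logistic", "gompertz", "modified_gompertz", "richards")

PARAM_NAMES = {
    "logistic": ("A", "t", "s"),
    "gompertz": ("A", "t", "s"),
    "richards": ("A", "t", "s", "q_tilde"),
    "modified_gompertz": ("A", "t", "s", "w", "l_shift"),
}

#: below this |q_tilde| the Richards curve is evaluated as its Gompertz limit
_Q_TILDE_EPS = 1e-6


class ModelError(ValueError):
    pass


def _safe_exp(x):
    return np.exp(np.clip(x, -700.0, 700.0))


def _check_params(model: str, params: dict) -> None:
    if model not in MODELS:
        raise ModelError(f"unknown model {model!r}")
    missing = [k for k in PARAM_NAMES[model] if k not in params]
    if missing:
        raise ModelError(f"{model}: missing parameters {missing}")
    if params["A"] <= 0 or params["t"] <= 0:
        raise ModelError(f"{model}: require A > 0 and t > 0")
    if model == "richards" and params["q_tilde"] <= -1:
        raise ModelError("richards: require q_tilde > -1")


def eval_model(model: str, params: dict, l) -> np.ndarray:
    """Evaluate a packing model on scales ``l`` (overflow-safe)."""
    _check_params(model, params)
    l = np.asarray(l, dtype=float)
    A, t, s = params["A"], params["t"], params["s"]
    if model == "logistic":
        return A / (1.0 + _safe_exp(4.0 * t / A * (s - l) + 2.0))
    if model == "gompertz":
        return A * np.exp(-_safe_exp(E * t / A * (s - l) + 1.0))
    if model == "modified_gompertz":
        base = A * np.exp(-_safe_exp(E * t / A * (s - l) + 1.0))
        return base + A * _safe_exp(params["w"] * (l - params["l_shift"]))
    # richards
    q = params["q_tilde"]
    if abs(q) < _Q_TILDE_EPS:
        return A * np.exp(-_safe_exp(E * t / A * (s - l) + 1.0))
    d = t / A * (1.0 + q) ** (1.0 + 1.0 / q)
    # q*b*exp(-d*l) written as q*exp(u) with u = 1 + q + d*(s - l)
    u = 1.0 + q + d * (s - l)
    base = 1.0 + q * _safe_exp(u)
    if q > 0:
        return A * base ** (-1.0 / q)
    out = np.zeros_like(base)
    pos = base > 0
    out[pos] = A * base[pos] ** (-1.0 / q)
    return out


def richards_d(params: dict) -> float:
    """Richards rate constant d = t/A*(1+q)^(1+1/q) (Gompertz limit e*t/A)."""
    A, t, q = params["A"], params["t"], params["q_tilde"]
    if abs(q) < _Q_TILDE_EPS:
        return E * t / A
    return t / A * (1.0 + q) ** (1.0 + 1.0 / q)


def inflection_point(model: str, params: dict,
                     l_bounds: tuple[float, float] | None = None) -> float:
    """Scale xi where the curve's second derivative vanishes (RDF maximum).

    Closed forms for logistic/gompertz/richards; for the modified Gompertz
    the first second-derivative sign change after s is located numerically
    on ``l_bounds`` (required for that model).
    """
    _check_params(model, params)
    A, t, s = params["A"], params["t"], params["s"]
    if model == "logistic":
        return s + A / (2.0 * t)
    if model == "gompertz":
        return s + A / (E * t)
    if model == "richards":
        q = params["q_tilde"]
        if abs(q) < _Q_TILDE_EPS:
            return s + A / (E * t)
        return s + (1.0 + q) / richards_d(params)
    if l_bounds is None:
        raise ModelError("modified_gompertz needs l_bounds for the numeric root")
    lo, hi = l_bounds
    h = (hi - lo) * 1e-5

    def d2(x):
        f = lambda y: float(eval_model(model, params, y))
        return (f(x + h) - 2.0 * f(x) + f(x - h)) / h**2

    grid = np.linspace(max(lo + 2 * h, s), hi - 2 * h, 400)
    vals = np.array([d2(x) for x in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ModelError("no inflection: second derivative has no sign change")
    i = sign_change[0]
    return float(brentq(d2, grid[i], grid[i + 1], xtol=1e-10))


def asymptote_onset(model: str, params: dict, *, o_mode: str = "tangent",
                    eps_asym: float = 0.01,
                    l_bounds: tuple[float, float] | None = None) -> float:
    """Scale o where the asymptote domain begins.

    ``tangent`` (default): the tangent at the inflection point reaches A,
    which for the logistic/Gompertz/Richards forms equals s + A/t exactly
    and makes t = A/(o-s) an identity.  ``threshold``: smallest l with
    n(l) >= (1-eps_asym)*A, solved on the curve.
    """
    _check_params(model, params)
    A, t, s = params["A"], params["t"], params["s"]
    if o_mode == "tangent":
        if model in ("logistic", "gompertz", "richards"):
            return s + A / t
        xi = inflection_point(model, params, l_bounds)
        n_xi = float(eval_model(model, params, xi))
        return xi + (A - n_xi) / t
    if o_mode == "threshold":
        target = (1.0 - eps_asym) * A
        f = lambda x: float(eval_model(model, params, x)) - target
        lo = s
        hi = s + 10.0 * A / t
        while f(hi) < 0 and hi < s + 1e6 * A / t:
            hi *= 2.0
        return float(brentq(f, lo, hi, xtol=1e-10))
    raise ModelError(f"unknown o_mode {o_mode!r}")


@dataclass
class PackingFit:
    """Result of fitting one sigmoid model to a normalized packing trace."""

    model: str
    params: dict
    xi: float
    o: float
    os_: float           # inflection-domain size o - s
    aic: float
    mafe: float          # mean absolute fitting error
    rss: float
    n_points: int
    converged: bool
    message: str = ""
    ci: dict = field(default_factory=dict)   # param -> (lo, hi)

    @property
    def A(self): return self.params["A"]

    @property
    def t(self): return self.params["t"]

    @property
    def s(self): return self.params["s"]

    @property
    def q_tilde(self): return self.params.get("q_tilde")

    @property
    def q(self):
        """Non-extensive entropic index q = 1 - q_tilde (Richards only)."""
        qt = self.params.get("q_tilde")
        return None if qt is None else 1.0 - qt


def _initial_guesses(model: str, l: np.ndarray, n: np.ndarray) -> list[np.ndarray]:
    A0 = float(np.max(n))
    slopes = np.diff(n) / np.diff(l)
    t0 = float(np.max(slopes)) if np.any(np.isfinite(slopes)) else 0.1
    t0 = max(t0, 1e-3)
    above = np.nonzero(n >= 0.1 * A0)[0]
    s0 = float(l[above[0]]) if len(above) else float(l[0])
    base = [A0, t0, max(s0, 0.0)]
    if model in ("logistic", "gompertz"):
        return [np.array(base)]
    if model == "richards":
        return [np.array(base + [q0]) for q0 in (0.2, 1.0, 2.0)]
    # modified_gompertz: start with a negligible second rise far to the right
    lmax = float(l[-1])
    return [np.array(base + [w0, lmax]) for w0 in (1e-3, 1e-2)]


def _bounds(model: str, l: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lmax = float(l[-1])
    lo = [1e-6, 1e-6, 0.0]
    hi = [1.5, np.inf, lmax]
    if model == "richards":
        lo, hi = lo + [-0.99], hi + [10.0]
    elif model == "modified_gompertz":
        lo, hi = lo + [0.0, 0.0], hi + [10.0, 2.0 * lmax]
    return np.array(lo), np.array(hi)


def fit_model(
    l,
    n,
    model: str,
    *,
    normalize: bool = True,
    o_mode: str = "tangent",
    eps_asym: float = 0.01,
) -> PackingFit:
    """Least-squares fit of one packing model with multi-start initialisation.

    The trace is max-normalized before fitting (disable with
    ``normalize=False`` if it already is).  Non-convergence (degenerate
    input, optimizer failure, or no admissible inflection) yields a flagged
    fit with diagnostics rather than an exception.
    """
    l = np.asarray(l, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(l) < 8:
        raise ModelError(f"need >= 8 points to fit, got {len(l)}")
    if normalize:
        m = np.max(n)
        if m > 0:
            n = n / m

    names = PARAM_NAMES[model]

    def _flagged(msg):
        return PackingFit(model=model, params=dict.fromkeys(names, np.nan),
                          xi=np.nan, o=np.nan, os_=np.nan, aic=np.inf,
                          mafe=np.nan, rss=np.inf, n_points=len(l),
                          converged=False, message=msg)

    span = np.max(n) - np.min(n)
    if span < 0.01 * max(np.max(np.abs(n)), 1e-12):
        return _flagged("degenerate trace: no sigmoid rise")

    lo, hi = _bounds(model, l)
    best = None
    for x0 in _initial_guesses(model, l, n):
        x0 = np.clip(x0, lo + 1e-12, np.where(np.isinf(hi), x0, hi))

        def resid(x):
            return eval_model(model, dict(zip(names, x)), l) - n

        try:
            res = least_squares(resid, x0, bounds=(lo, hi),
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return _flagged("optimizer failed to converge from all starts")

    params = dict(zip(names, map(float, best.x)))
    fitted = eval_model(model, params, l)
    rss = float(np.sum((fitted - n) ** 2))
    mafe = float(np.mean(np.abs(fitted - n)))
    k = len(names)
    npts = len(l)
    aic = npts * np.log(max(rss, 1e-300) / npts) + 2 * k

    l_bounds = (float(l[0]), float(l[-1]))
    try:
        xi = inflection_point(model, params, l_bounds)
        o = asymptote_onset(model, params, o_mode=o_mode, eps_asym=eps_asym,
                            l_bounds=l_bounds)
    except ModelError as exc:
        fit = _flagged(f"converged parameters but {exc}")
        fit.params, fit.aic, fit.mafe, fit.rss = params, aic, mafe, rss
        return fit

    return PackingFit(model=model, params=params, xi=float(xi), o=float(o),
                      os_=float(o - params["s"]), aic=float(aic), mafe=mafe,
                      rss=rss, n_points=npts, converged=True, message="ok")


def select_model(
    l, n, *, models: tuple[str, ...] = MODELS, aicc: bool = False, **kw
) -> PackingFit:
    """Fit all candidate models and return the minimum-AIC converged fit."""
    fits = []
    for model in models:
        try:
            fits.append(fit_model(l, n, model, **kw))
        except ModelError:
            raise
    converged = [f for f in fits if f.converged]
    if not converged:
        msgs = "; ".join(f"{f.model}: {f.message}" for f in fits)
        raise ModelError(f"no packing model converged ({msgs})")

    def score(f: PackingFit) -> float:
        if not aicc:
            return f.aic
        k = len(PARAM_NAMES[f.model])
        denom = f.n_points - k - 1
        return f.aic + (2.0 * k * (k + 1) / denom if denom > 0 else np.inf)

    return min(converged, key=score)


def bootstrap_ci(
    l,
    n,
    fit: PackingFit,
    n_boot: int = 100,
    seed: int = 0,
    *,
    level: float = 0.95,
    normalize: bool = True,
) -> dict:
    """Case-resampling bootstrap percentile intervals for fit parameters.

    Resampled fits start from the point estimate (single-start); replicates
    that fail to converge are dropped, with a warning if more than half do.
    The intervals are stored on ``fit.ci`` and returned.
    """
    if not fit.converged:
        raise ModelError("cannot bootstrap a non-converged fit")
    l = np.asarray(l, dtype=float)
    n = np.asarray(n, dtype=float)
    if normalize:
        m = np.max(n)
        if m > 0:
            n = n / m
    names = PARAM_NAMES[fit.model]
    x_hat = np.array([fit.params[k] for k in names])
    lo_b, hi_b = _bounds(fit.model, l)
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_boot):
        idx = np.sort(rng.integers(0, len(l), size=len(l)))
        lb, nb = l[idx], n[idx]

        def resid(x):
            return eval_model(fit.model, dict(zip(names, x)), lb) - nb

        try:
            res = least_squares(resid, np.clip(x_hat, lo_b + 1e-12, None),
                                bounds=(lo_b, hi_b), xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if res.success:
            samples.append(res.x)
    if len(samples) < n_boot / 2:
        warnings.warn(
            f"only {len(samples)}/{n_boot} bootstrap replicates converged; "
            "intervals may be too wide"
        )
    if not samples:
        raise ModelError("all bootstrap replicates failed")
    arr = np.array(samples)
    tail = (1.0 - level) / 2.0 * 100.0
    ci = {
        name: (float(np.percentile(arr[:, j], tail)),
               float(np.percentile(arr[:, j], 100.0 - tail)))
        for j, name in enumerate(names)
    }
    fit.ci = ci
    return ci
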